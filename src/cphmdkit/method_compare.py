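"""Cross-method pKa benchmarking: shifts from model pKa, pairwise RMSD and
Pearson correlation matrices, and per-method RMSD against a reference
predictor.

Masking policy.  Residues censored in the *reference* method (anomalously
ionizing residues whose pKa lies outside the scanned window) are excluded
from every statistic, and on top of that each pair drops residues censored
in either of its two methods.  Because a pKa shift is predicted − model and
the model pKa cancels in any between-method difference, pairwise RMSDs are
identical whether computed on shifts or on raw pKa values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .io_formats import PkaTable, ResidueComposition

__all__ = ["ShiftTable", "ComparisonReport", "pka_shifts", "rmsd", "pearson",
           "compare_report"]


@dataclass
class ShiftTable:
    """Residues × methods frame of pKa shifts (predicted − model pKa).

    ``mask`` is True where the cell is usable (uncensored); masked-out cells
    are NaN in ``shifts`` and never enter statistics.
    """

    shifts: pd.DataFrame
    mask: pd.DataFrame


def pka_shifts(table: PkaTable, composition: ResidueComposition) -> ShiftTable:
    """Shift = predicted − model pKa per uncensored cell."""
    model = pd.Series(
        {res: composition.model_pka(res) for res in table.residues}, dtype=float
    )
    values = table.values()
    mask = ~table.censored()
    shifts = values.sub(model, axis=0).where(mask)
    return ShiftTable(shifts=shifts, mask=mask)


def rmsd(a, b, mask=None) -> float:
    """Root-mean-square deviation over jointly usable cells."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    use = np.isfinite(a) & np.isfinite(b)
    if mask is not None:
        use &= np.asarray(mask, dtype=bool)
    if not use.any():
        raise DataError("no jointly usable cells for RMSD")
    d = a[use] - b[use]
    return float(np.sqrt(np.mean(d * d)))


def pearson(a, b, mask=None) -> float:
    """Sample Pearson correlation over jointly usable cells."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    use = np.isfinite(a) & np.isfinite(b)
    if mask is not None:
        use &= np.asarray(mask, dtype=bool)
    if use.sum() < 3:
        raise DataError("Pearson correlation needs at least 3 usable cells")
    if np.std(a[use]) == 0 or np.std(b[use]) == 0:
        raise DataError("degenerate variance in Pearson correlation")
    return float(stats.pearsonr(a[use], b[use]).statistic)


@dataclass
class ComparisonReport:
    """Pairwise benchmark matrices over a pKa table.

    ``pairwise_rmsd`` and ``pairwise_r`` are symmetric method × method
    frames (diagonal 0 and 1 respectively); ``n_used`` counts the residues
    entering each pair; ``reference_rmsd`` is each method's RMSD against the
    designated reference.
    """

    pairwise_rmsd: pd.DataFrame
    pairwise_r: pd.DataFrame
    n_used: pd.DataFrame
    reference_rmsd: pd.Series
    reference: str
    excluded_residues: list[str]

    def rounded(self, decimals: int = 2) -> dict[str, pd.DataFrame]:
        return {
            "pairwise_rmsd": self.pairwise_rmsd.round(decimals),
            "pairwise_r": self.pairwise_r.round(decimals),
            "n_used": self.n_used,
            "reference_rmsd": self.reference_rmsd.round(decimals).to_frame("rmsd"),
        }


def compare_report(
    table: PkaTable,
    reference: str,
    composition: ResidueComposition | None = None,
) -> ComparisonReport:
    """Full pairwise RMSD/Pearson matrices plus per-method RMSD vs reference.

    Residues censored in the reference are excluded everywhere; remaining
    censored cells are dropped pairwise.  ``composition`` is only needed
    when shift statistics are requested elsewhere — pairwise RMSDs do not
    depend on it (the model pKa cancels).
    """
    if reference not in table.methods:
        raise DataError(f"reference method {reference!r} not in table")
    values = table.values()
    usable = ~table.censored()
    keep = usable[reference]
    excluded = [res for res, ok in keep.items() if not ok]
    methods = list(table.methods)
    n = len(methods)
    rmsd_m = pd.DataFrame(np.zeros((n, n)), index=methods, columns=methods)
    r_m = pd.DataFrame(np.eye(n), index=methods, columns=methods)
    n_used = pd.DataFrame(0, index=methods, columns=methods, dtype=int)
    for i, ma in enumerate(methods):
        for j, mb in enumerate(methods):
            if j < i:
                continue
            mask = keep & usable[ma] & usable[mb]
            n_used.loc[ma, mb] = n_used.loc[mb, ma] = int(mask.sum())
            if i == j:
                continue
            if mask.sum() == 0:
                warnings.warn(
                    f"no usable residues for pair ({ma}, {mb}); pair excluded"
                )
                rmsd_m.loc[ma, mb] = rmsd_m.loc[mb, ma] = np.nan
                r_m.loc[ma, mb] = r_m.loc[mb, ma] = np.nan
                continue
            val = rmsd(values[ma], values[mb], mask)
            rmsd_m.loc[ma, mb] = rmsd_m.loc[mb, ma] = val
            try:
                rr = pearson(values[ma], values[mb], mask)
            except DataError:
                rr = np.nan
            r_m.loc[ma, mb] = r_m.loc[mb, ma] = rr
    reference_rmsd = rmsd_m[reference].drop(index=reference)
    return ComparisonReport(
        pairwise_rmsd=rmsd_m,
        pairwise_r=r_m,
        n_used=n_used,
        reference_rmsd=reference_rmsd,
        reference=reference,
        excluded_residues=excluded,
    )
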