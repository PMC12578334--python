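"""Readers and writers for λ-trajectory files (GROMACS xvg dialect), pKa
prediction tables with censored entries, and residue-composition tables.

The xvg dialect accepted here is the one written by ``gmx cphmd``: lines
beginning with ``#`` or ``@`` are metadata, every other line is a
whitespace-delimited numeric record whose first column is the simulation
time (ns) and whose remaining columns are λ-coordinates, one per titratable
site.  λ is the continuous protonation coordinate of λ-dynamics: values near
0 mean protonated, values near 1 mean deprotonated, and slight overshoots
outside [0, 1] are physical and preserved verbatim.

pKa tables are delimited text with residue labels in the first column and
one column per prediction method.  Cells are either numeric or censored
tokens ``<x`` / ``>x`` meaning the residue never crossed half-protonation
within the scanned pH range (pKa below/above the scan limit).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ParseError

__all__ = [
    "LambdaTrajectory",
    "Censor",
    "PkaEstimate",
    "PkaTable",
    "ResidueComposition",
    "ACIDIC_TYPES",
    "BASIC_TYPES",
    "RESIDUE_TYPES",
    "read_lambda_xvg",
    "write_lambda_xvg",
    "parse_pka_token",
    "format_pka_token",
    "read_pka_table",
    "read_composition",
]

ACIDIC_TYPES = frozenset({"ASP", "GLU"})
BASIC_TYPES = frozenset({"HIS", "ARG", "LYS"})
RESIDUE_TYPES = ACIDIC_TYPES | BASIC_TYPES


@dataclass
class LambdaTrajectory:
    """One titratable site's λ(t) series at a fixed solution pH.

    Parameters
    ----------
    residue_id : str
        Opaque residue label, e.g. ``"D37"``.  Used as a join key only.
    monomer, replica : int
        Indices locating the trajectory in the monomer × replica hierarchy.
    pH : float
        Solution pH of the simulation.
    time : ndarray
        Strictly increasing simulation times in ns.
    lam : ndarray
        λ values, same length as ``time``; typically within [-0.1, 1.1].
    """

    residue_id: str
    monomer: int
    replica: int
    pH: float
    time: np.ndarray
    lam: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        if self.time.ndim != 1 or self.lam.ndim != 1:
            raise DataError("time and lam must be one-dimensional")
        if self.time.size != self.lam.size:
            raise DataError(
                f"time ({self.time.size}) and lam ({self.lam.size}) differ in length"
            )
        if self.time.size < 1:
            raise DataError("trajectory must contain at least one frame")
        if self.time.size > 1 and not np.all(np.diff(self.time) > 0):
            raise DataError("time must be strictly increasing")

    def __len__(self) -> int:
        return int(self.time.size)


def read_lambda_xvg(
    path,
    residue_id: str = "",
    monomer: int = 0,
    replica: int = 0,
    pH: float = math.nan,
    lam_column: int = 2,
) -> LambdaTrajectory:
    """Read one λ-trajectory from an xvg file.

    ``lam_column`` is 1-based; the default (2) selects the first λ column of
    a ``time λ1 [λ2 ...]`` layout.  Lines starting with ``#`` or ``@`` are
    skipped; any other non-numeric line raises :class:`ParseError` naming
    the offending line number.
    """
    path = Path(path)
    if lam_column < 2:
        raise ValueError("lam_column is 1-based and must be >= 2 (column 1 is time)")
    times: list[float] = []
    lams: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "@")):
                continue
            fields = line.split()
            if len(fields) < lam_column:
                raise ParseError(
                    f"{path}:{lineno}: expected at least {lam_column} columns, "
                    f"got {len(fields)}"
                )
            try:
                t = float(fields[0])
                lam = float(fields[lam_column - 1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric value ({exc})") from None
            times.append(t)
            lams.append(lam)
    if not times:
        raise ParseError(f"{path}: no data lines found")
    return LambdaTrajectory(
        residue_id=residue_id,
        monomer=monomer,
        replica=replica,
        pH=pH,
        time=np.array(times),
        lam=np.array(lams),
    )


def write_lambda_xvg(traj: LambdaTrajectory, path) -> Path:
    """Write a trajectory in the two-column xvg dialect.

    Values are written at full repr precision, so a read/write round trip
    reproduces ``time`` and ``lam`` exactly; λ outside [0, 1] is preserved
    verbatim (no clipping at the I/O layer).
    """
    if len(traj) < 1:  # defensive; the dataclass already forbids this
        raise DataError("refusing to write an empty trajectory")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"@ title \"lambda trajectory {traj.residue_id}\"\n")
        fh.write(f"# residue {traj.residue_id} monomer {traj.monomer} "
                 f"replica {traj.replica} pH {traj.pH!r}\n")
        fh.write("@ xaxis label \"time (ns)\"\n")
        fh.write("@ yaxis label \"lambda\"\n")
        for t, lam in zip(traj.time, traj.lam):
            fh.write(f"{float(t)!r} {float(lam)!r}\n")
    return path


# ---------------------------------------------------------------------------
# pKa tables


@dataclass(frozen=True)
class Censor:
    """A censored pKa bound: ``kind`` is ``"below"`` or ``"above"``.

    ``below(1)`` encodes a table cell ``< 1`` (the residue stayed
    deprotonated down to pH 1); ``above(8)`` encodes ``> 8``.
    """

    kind: str
    limit: float

    def __post_init__(self) -> None:
        if self.kind not in ("below", "above"):
            raise ValueError(f"censor kind must be 'below' or 'above', got {self.kind!r}")


@dataclass
class PkaEstimate:
    """A numeric pKa or a censored bound, with optional uncertainty.

    Exactly one of ``value`` / ``censor`` is set.  ``sd`` is a replica-based
    standard deviation (pH units); ``hill_n`` and ``rss`` carry fit metadata
    when the estimate came from a curve fit.
    """

    value: float | None = None
    censor: Censor | None = None
    sd: float | None = None
    hill_n: float | None = None
    rss: float | None = None

    def __post_init__(self) -> None:
        if (self.value is None) == (self.censor is None):
            raise ValueError("exactly one of value/censor must be set")
        if self.sd is not None and self.sd < 0:
            raise ValueError("sd must be non-negative")

    @property
    def is_censored(self) -> bool:
        return self.censor is not None


_NUM = r"[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?"
_TOKEN_RE = re.compile(rf"^\s*(?:(?P<cmp>[<>])\s*)?(?P<num>{_NUM})\s*$")


def parse_pka_token(token: str) -> PkaEstimate:
    """Parse one pKa table cell: a number, ``<x`` or ``>x`` (spaces allowed)."""
    m = _TOKEN_RE.match(str(token))
    if m is None:
        raise ParseError(f"unsupported pKa token {token!r}")
    num = float(m.group("num"))
    cmp_ = m.group("cmp")
    if cmp_ is None:
        return PkaEstimate(value=num)
    kind = "below" if cmp_ == "<" else "above"
    return PkaEstimate(censor=Censor(kind, num))


def format_pka_token(est: PkaEstimate) -> str:
    if est.is_censored:
        sym = "<" if est.censor.kind == "below" else ">"
        return f"{sym} {est.censor.limit:g}"
    return f"{est.value:g}"


@dataclass
class PkaTable:
    """Residues × methods matrix of :class:`PkaEstimate`, the unit of benchmarking."""

    residues: list[str]
    methods: list[str]
    entries: dict[tuple[str, str], PkaEstimate]

    def __post_init__(self) -> None:
        if len(set(self.residues)) != len(self.residues):
            raise DataError("duplicate residue labels in pKa table")
        if len(set(self.methods)) != len(self.methods):
            raise DataError("duplicate method labels in pKa table")
        for res in self.residues:
            for meth in self.methods:
                if (res, meth) not in self.entries:
                    raise DataError(f"missing cell for residue {res!r}, method {meth!r}")

    def get(self, residue: str, method: str) -> PkaEstimate:
        return self.entries[(residue, method)]

    def values(self) -> pd.DataFrame:
        """Numeric pKa values as a residues × methods frame; censored cells are NaN."""
        data = {
            meth: [
                self.entries[(res, meth)].value
                if not self.entries[(res, meth)].is_censored
                else np.nan
                for res in self.residues
            ]
            for meth in self.methods
        }
        return pd.DataFrame(data, index=self.residues, dtype=float)

    def censored(self) -> pd.DataFrame:
        """Boolean residues × methods frame, True where the cell is censored."""
        data = {
            meth: [self.entries[(res, meth)].is_censored for res in self.residues]
            for meth in self.methods
        }
        return pd.DataFrame(data, index=self.residues, dtype=bool)


def read_pka_table(path, delimiter: str | None = None) -> PkaTable:
    """Read a residues × methods pKa table from delimited text.

    First column: residue labels (kept as opaque strings).  Remaining
    columns: one per method, cells numeric or censored (``<x`` / ``>x``).
    Lines starting with ``#`` are comments.  The delimiter is auto-detected
    unless given.
    """
    try:
        df = pd.read_csv(
            path,
            sep=delimiter,
            engine="python",
            comment="#",
            index_col=0,
            dtype=str,
            skipinitialspace=True,
        )
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty pKa table") from None
    residues = [str(r).strip() for r in df.index]
    if len(set(residues)) != len(residues):
        dupes = sorted({r for r in residues if residues.count(r) > 1})
        raise ParseError(f"{path}: duplicate residue label(s) {dupes}")
    methods = [str(c).strip() for c in df.columns]
    entries: dict[tuple[str, str], PkaEstimate] = {}
    for res, (_, row) in zip(residues, df.iterrows()):
        for meth, cell in zip(methods, row):
            try:
                entries[(res, meth)] = parse_pka_token(cell)
            except ParseError:
                raise ParseError(
                    f"{path}: unparseable cell {cell!r} for residue {res!r}, "
                    f"method {meth!r}"
                ) from None
    return PkaTable(residues=residues, methods=methods, entries=entries)


# ---------------------------------------------------------------------------
# residue composition


@dataclass
class ResidueComposition:
    """Per-residue type and model-compound pKa, the input of net-charge sums.

    ``frame`` has columns ``residue`` (label), ``res_type`` (one of
    ASP/GLU/HIS/ARG/LYS) and ``model_pka`` (pH units).  The type determines
    acid/base polarity: ASP/GLU are acidic (charge −1 when deprotonated),
    HIS/ARG/LYS basic (+1 when protonated).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["residue", "res_type", "model_pka"]
        if list(self.frame.columns) != required:
            self.frame = self.frame[required]
        self.frame = self.frame.reset_index(drop=True)
        bad = set(self.frame["res_type"]) - RESIDUE_TYPES
        if bad:
            raise DataError(f"unsupported residue type(s): {sorted(bad)}")
        if self.frame["model_pka"].isna().any():
            missing = self.frame.loc[self.frame["model_pka"].isna(), "residue"].tolist()
            raise DataError(f"missing model_pka for residue(s): {missing}")
        if self.frame["residue"].duplicated().any():
            dupes = self.frame.loc[self.frame["residue"].duplicated(), "residue"].tolist()
            raise DataError(f"duplicate residue label(s) in composition: {dupes}")

    def __len__(self) -> int:
        return len(self.frame)

    def model_pka(self, residue: str) -> float:
        sel = self.frame.loc[self.frame["residue"] == residue, "model_pka"]
        if sel.empty:
            raise DataError(f"residue {residue!r} not in composition")
        return float(sel.iloc[0])

    def res_type(self, residue: str) -> str:
        sel = self.frame.loc[self.frame["residue"] == residue, "res_type"]
        if sel.empty:
            raise DataError(f"residue {residue!r} not in composition")
        return str(sel.iloc[0])


def read_composition(path, delimiter: str | None = None) -> ResidueComposition:
    """Read a residue-composition table: columns label, type, model_pka.

    A header row is optional.  An empty file yields an empty composition
    (net charge identically zero).
    """
    content = Path(path).read_text()
    if not any(
        line.strip() and not line.lstrip().startswith("#")
        for line in content.splitlines()
    ):
        return ResidueComposition(
            pd.DataFrame(columns=["residue", "res_type", "model_pka"]).astype(
                {"model_pka": float}
            )
        )
    try:
        df = pd.read_csv(
            path,
            sep=delimiter,
            engine="python",
            comment="#",
            header=None,
            dtype=str,
            skipinitialspace=True,
        )
    except pd.errors.EmptyDataError:
        return ResidueComposition(
            pd.DataFrame(columns=["residue", "res_type", "model_pka"]).astype(
                {"model_pka": float}
            )
        )
    if df.shape[1] < 3:
        raise ParseError(f"{path}: expected 3 columns (residue, type, model_pka)")
    df = df.iloc[:, :3]
    df.columns = ["residue", "res_type", "model_pka"]
    # drop a header row if the third column is not numeric there
    first = str(df.iloc[0]["model_pka"])
    try:
        float(first)
    except ValueError:
        df = df.iloc[1:]
    if df.empty:
        return ResidueComposition(
            pd.DataFrame(columns=["residue", "res_type", "model_pka"]).astype(
                {"model_pka": float}
            )
        )
    out = pd.DataFrame(
        {
            "residue": df["residue"].astype(str).str.strip(),
            "res_type": df["res_type"].astype(str).str.strip().str.upper(),
        }
    )
    try:
        out["model_pka"] = df["model_pka"].astype(float).to_numpy()
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric model_pka ({exc})") from None
    return ResidueComposition(out)
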