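"""Net charge of a protein (per monomer) as a function of pH.

Each acidic residue (Asp/Glu) contributes −(1 − theta) elementary charges
and each basic residue (His/Arg/Lys) +theta, where theta is its protonated
fraction at the given pH — Henderson–Hasselbalch at the residue's assigned
pKa.  Residues with a censored pKa never titrate inside the scanned window
and enter as fixed charges: censored-below means permanently deprotonated
(theta = 0), censored-above permanently protonated (theta = 1).  Basic
residues without an assigned pKa default to fully protonated, the usual
situation over an acidic scan window.

The module also provides the model-pKa null curve, the pH-2/pH-8
normalization used to overlay charge curves with reversal-potential
measurements, and an effective Hill characterization of the aggregate
charge transition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DataError
from .io_formats import ACIDIC_TYPES, BASIC_TYPES, RESIDUE_TYPES, PkaEstimate, \
    ResidueComposition
from .titration_fit import HillParameters, fit_hill, hh_theta

__all__ = [
    "ChargeCurve",
    "residue_charge",
    "net_charge_curve",
    "null_model_curve",
    "normalize_curve",
    "effective_hill",
]


@dataclass
class ChargeCurve:
    """Net charge Q(pH) in elementary charges, labelled by the pKa source."""

    pH: np.ndarray
    Q: np.ndarray
    method: str = ""

    def __post_init__(self) -> None:
        self.pH = np.asarray(self.pH, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        if self.pH.size != self.Q.size:
            raise DataError("pH and Q grids are not aligned")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"pH": self.pH, "Q": self.Q})


def residue_charge(res_type: str, theta) -> np.ndarray | float:
    """Charge of one residue at protonated fraction ``theta``.

    Acids are neutral when protonated (charge −(1−theta)); bases carry the
    proton's charge (+theta).
    """
    theta = np.asarray(theta, dtype=float)
    if np.any((theta < 0) | (theta > 1)):
        raise DataError("theta must lie in [0, 1]")
    if res_type in ACIDIC_TYPES:
        q = -(1.0 - theta)
    elif res_type in BASIC_TYPES:
        q = +theta
    else:
        raise DataError(f"unsupported residue type {res_type!r}")
    return float(q) if q.ndim == 0 else q


def _theta_of(res_type: str, pka, pH: np.ndarray) -> np.ndarray:
    if isinstance(pka, PkaEstimate):
        if pka.is_censored:
            fixed = 0.0 if pka.censor.kind == "below" else 1.0
            return np.full_like(pH, fixed)
        pka = pka.value
    if pka is None:
        if res_type in BASIC_TYPES:
            return np.ones_like(pH)  # default protonated over an acidic scan
        raise DataError(f"acidic residue of type {res_type} needs a pKa")
    return hh_theta(pH, float(pka))


def net_charge_curve(
    assignments: Iterable[tuple[str, object]], pH_grid, method: str = ""
) -> ChargeCurve:
    """Sum residue charges over a pH grid.

    ``assignments`` yields ``(res_type, pka)`` pairs per residue, where
    ``pka`` is a float, a :class:`PkaEstimate` (possibly censored), or None
    (allowed for basic residues only: fixed fully protonated).
    """
    pH = np.asarray(pH_grid, dtype=float)
    Q = np.zeros_like(pH)
    n = 0
    for res_type, pka in assignments:
        if res_type not in RESIDUE_TYPES:
            raise DataError(f"unsupported residue type {res_type!r}")
        Q = Q + residue_charge(res_type, _theta_of(res_type, pka, pH))
        n += 1
    return ChargeCurve(pH=pH, Q=Q, method=method)


def null_model_curve(composition: ResidueComposition, pH_grid) -> ChargeCurve:
    """Net charge with every residue at its model-compound pKa."""
    assignments = [
        (row.res_type, float(row.model_pka)) for row in composition.frame.itertuples()
    ]
    return net_charge_curve(assignments, pH_grid, method="null_model")


def normalize_curve(curve, pH_lo: float = 2.0, pH_hi: float = 8.0) -> np.ndarray:
    """Rescale a curve to 1 at ``pH_lo`` and 0 at ``pH_hi``.

    ``curve`` is a :class:`ChargeCurve` or a ``(pH, values)`` pair; anchor
    values are linearly interpolated when the anchors fall between grid
    points.  Anchors outside the grid, or equal anchor values, are errors.
    """
    if isinstance(curve, ChargeCurve):
        pH, v = curve.pH, curve.Q
    else:
        pH, v = curve
        pH = np.asarray(pH, dtype=float)
        v = np.asarray(v, dtype=float)
    if pH_lo < pH.min() or pH_hi > pH.max():
        raise DataError("normalization anchors outside the curve's pH range")
    v_lo = float(np.interp(pH_lo, pH, v))
    v_hi = float(np.interp(pH_hi, pH, v))
    denom = v_lo - v_hi
    if abs(denom) < 1e-12:
        raise DataError("anchor values are equal; normalization undefined")
    return (v - v_hi) / denom


def effective_hill(curve: ChargeCurve) -> HillParameters:
    """Hill characterization of the aggregate charge transition.

    The curve is normalized with its own grid endpoints as anchors (1 at the
    acidic end, 0 at the basic end) and fitted to the Hill form; the
    effective pKa is the midpoint of the normalized transition and n its
    steepness — shallower than 1 whenever the underlying sites titrate at
    spread-out pKa values.
    """
    norm = normalize_curve(curve, pH_lo=float(curve.pH.min()),
                           pH_hi=float(curve.pH.max()))
    return fit_hill((curve.pH, norm), force=True)
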