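"""Seeded generator of λ-trajectories with prescribed titration behaviour.

A titratable site is modelled as a hidden two-level stochastic process:

* a (possibly trivial) conformer chain — the site hops between discrete
  conformational microstates, each carrying its own pKa.  Hops are a
  discrete-time refresh process: at every frame the conformer is resampled
  from the stationary weights with probability ``1 - exp(-dt/exchange_time)``,
  so the long-run conformer occupancies equal the weights exactly and the
  mean time between refresh events is ``exchange_time``.
* a protonation chain — within the current conformer, the protonated/
  deprotonated state is a two-state Markov chain whose stationary protonated
  probability is the Henderson–Hasselbalch fraction
  ``theta = 1/(1 + 10**(pH - pKa))`` of that conformer and whose relaxation
  time (1/(k_on + k_off)) is ``proto_relax_time``.

The emitted λ is 0 (protonated) or 1 (deprotonated) plus Gaussian noise,
truncated to [-0.1, 1.1] — a deliberately minimal stand-in for λ-dynamics
output: downstream analysis only senses occupancy and correlation time, not
the inertial dynamics of the λ coordinate.

``theta_true`` is the closed-form occupancy oracle every downstream stage is
validated against: the weighted mixture of per-conformer HH fractions.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .errors import DataError
from .io_formats import LambdaTrajectory, write_lambda_xvg

__all__ = [
    "TitrationModel",
    "PanelSpec",
    "theta_true",
    "stationary_se",
    "simulate_lambda",
    "generate_dataset",
]

#: default frame spacing of the emitted λ series (ns)
DEFAULT_FRAME_INTERVAL = 0.01
#: default protonation-state relaxation time 1/(k_on+k_off) (ns).  Saved λ
#: frames of constant-pH λ-dynamics runs are nearly decorrelated at typical
#: output strides; a relaxation time on the order of the frame spacing
#: reproduces the observed ~10 ns convergence of replica-averaged cumulative
#: protonation fractions.
DEFAULT_PROTO_RELAX_TIME = 0.01
#: default mean conformer refresh time (ns); long compared to protonation
#: kinetics, so minority conformers show up as rare, persistent excursions.
DEFAULT_EXCHANGE_TIME = 50.0
#: default Gaussian spread of λ around 0/1
DEFAULT_EMISSION_SD = 0.05


@dataclass(frozen=True)
class TitrationModel:
    """Generative description of one titratable site.

    ``conformers`` is a sequence of (weight, pKa) pairs; weights must be
    positive and sum to 1.  All times are in ns.  ``emission_sd`` must stay
    within [0, 0.15] so that the 0.2/0.8 λ thresholds cleanly separate the
    protonated and deprotonated emission modes.
    """

    conformers: tuple[tuple[float, float], ...]
    exchange_time: float = DEFAULT_EXCHANGE_TIME
    proto_relax_time: float = DEFAULT_PROTO_RELAX_TIME
    emission_sd: float = DEFAULT_EMISSION_SD
    frame_interval: float = DEFAULT_FRAME_INTERVAL

    def __post_init__(self) -> None:
        conf = tuple((float(w), float(p)) for w, p in self.conformers)
        object.__setattr__(self, "conformers", conf)
        if not conf:
            raise DataError("model needs at least one conformer")
        weights = np.array([w for w, _ in conf])
        if np.any(weights <= 0):
            raise DataError("conformer weights must be positive")
        if abs(weights.sum() - 1.0) > 1e-9:
            raise DataError(f"conformer weights must sum to 1, got {weights.sum()}")
        for name in ("exchange_time", "proto_relax_time", "frame_interval"):
            if getattr(self, name) <= 0:
                raise DataError(f"{name} must be positive")
        if not 0.0 <= self.emission_sd <= 0.15:
            raise DataError("emission_sd must lie in [0, 0.15]")

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for w, _ in self.conformers])

    @property
    def pkas(self) -> np.ndarray:
        return np.array([p for _, p in self.conformers])


def theta_true(pH, model: TitrationModel) -> np.ndarray | float:
    """Closed-form protonated fraction: Σ_k w_k / (1 + 10**(pH - pKa_k)).

    Vectorized over ``pH``; returns a scalar for scalar input.
    """
    pH = np.asarray(pH, dtype=float)
    w = model.weights
    pk = model.pkas
    th = np.sum(w / (1.0 + 10.0 ** (pH[..., None] - pk)), axis=-1)
    return float(th) if th.ndim == 0 else th


def stationary_se(pH: float, duration: float, model: TitrationModel) -> float:
    """Standard error of the time-averaged occupancy of one trajectory.

    The variance of the protonation indicator splits into a fast
    within-conformer part, E_k[theta_k(1-theta_k)], decorrelating with
    ``proto_relax_time``, and a between-conformer part,
    Var_k(theta_k), decorrelating with ``exchange_time``.  Each part is
    inflated by the exact autocorrelation factor (1+g)/(1-g) of its discrete
    refresh chain (g = exp(-dt/tau)), which reduces to the familiar
    effective-sample-size form duration/(2*tau) when dt << tau.
    """
    n = max(int(round(duration / model.frame_interval)), 1)
    w = model.weights
    th_k = 1.0 / (1.0 + 10.0 ** (pH - model.pkas))
    within = float(np.sum(w * th_k * (1.0 - th_k)))
    between = float(np.sum(w * th_k**2) - np.sum(w * th_k) ** 2)
    g_p = np.exp(-model.frame_interval / model.proto_relax_time)
    g_c = np.exp(-model.frame_interval / model.exchange_time)
    var = (
        within * (1.0 + g_p) / (1.0 - g_p) + between * (1.0 + g_c) / (1.0 - g_c)
    ) / n
    return float(np.sqrt(var))


def _last_event_value(values: np.ndarray, events: np.ndarray, initial):
    """values[i] of the most recent event at or before i, else ``initial``."""
    idx = np.where(events, np.arange(values.size), -1)
    last = np.maximum.accumulate(idx)
    out = np.where(last >= 0, values[np.clip(last, 0, None)], initial)
    return out


def simulate_lambda(
    model: TitrationModel,
    pH: float,
    duration: float,
    seed: int,
    residue_id: str = "",
    monomer: int = 0,
    replica: int = 0,
    return_hidden: bool = False,
):
    """Simulate one λ-trajectory of length ``duration`` ns.

    Identical ``(model, pH, duration, seed)`` give bit-identical output.
    With ``return_hidden=True`` returns ``(traj, conformer_idx, protonated)``
    exposing the hidden chains, e.g. for protonation/conformation trace
    correlation studies.
    """
    dt = model.frame_interval
    if duration < 10 * dt:
        raise DataError("duration must be at least 10 frame intervals")
    n = int(round(duration / dt))
    rng = np.random.default_rng(seed)

    # Fixed draw order, independent of the number of conformers, so that
    # degenerate mixtures (all pKa equal) reproduce the single-conformer
    # trajectory bit for bit under the same seed.
    u_init_conf = rng.random()
    u_init_state = rng.random()
    u_switch = rng.random(n)
    u_choice = rng.random(n)
    u_refresh = rng.random(n)
    u_state = rng.random(n)
    eps = rng.standard_normal(n)

    cumw = np.cumsum(model.weights)
    k = len(model.conformers)
    if k == 1:
        conf = np.zeros(n, dtype=np.intp)
    else:
        p_switch = 1.0 - np.exp(-dt / model.exchange_time)
        choices = np.searchsorted(cumw, u_choice, side="right").astype(np.intp)
        init_conf = int(np.searchsorted(cumw, u_init_conf, side="right"))
        conf = _last_event_value(choices, u_switch < p_switch, init_conf).astype(np.intp)

    theta_conf = 1.0 / (1.0 + 10.0 ** (pH - model.pkas))  # per-conformer HH
    r = 1.0 - np.exp(-dt / model.proto_relax_time)
    refresh = u_refresh < r
    candidate = u_state < theta_conf[conf]
    init_conf_idx = 0 if k == 1 else int(np.searchsorted(cumw, u_init_conf, side="right"))
    init_state = u_init_state < theta_conf[init_conf_idx]
    protonated = _last_event_value(candidate, refresh, init_state).astype(bool)

    lam = np.where(protonated, 0.0, 1.0) + model.emission_sd * eps
    lam = np.clip(lam, -0.1, 1.1)
    time = dt * np.arange(1, n + 1)
    traj = LambdaTrajectory(
        residue_id=residue_id, monomer=monomer, replica=replica, pH=pH,
        time=time, lam=lam,
    )
    if return_hidden:
        return traj, conf, protonated
    return traj


# ---------------------------------------------------------------------------
# panel generation


@dataclass
class PanelSpec:
    """A residue panel × pH grid × monomer/replica layout to synthesize.

    Defaults mirror a typical constant-pH study design: pH 1..8 in unit
    steps, 3 monomers × 3 replicas.
    """

    residues: list[tuple[str, TitrationModel]]
    pH_grid: Sequence[float] = tuple(range(1, 9))
    n_monomers: int = 3
    n_replicas: int = 3
    duration: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        grid = np.asarray(self.pH_grid, dtype=float)
        if grid.size < 1 or (grid.size > 1 and not np.all(np.diff(grid) > 0)):
            raise DataError("pH grid must be non-empty and strictly increasing")
        self.pH_grid = tuple(float(p) for p in grid)
        if self.n_monomers < 1 or self.n_replicas < 1:
            raise DataError("monomer and replica counts must be >= 1")
        labels = [lab for lab, _ in self.residues]
        if len(set(labels)) != len(labels):
            raise DataError("duplicate residue labels in panel")

    @classmethod
    def from_yaml(cls, path) -> "PanelSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        residues = []
        for entry in raw["residues"]:
            kwargs = {}
            for key in ("exchange_time", "proto_relax_time", "emission_sd",
                        "frame_interval"):
                if key in entry:
                    kwargs[key] = float(entry[key])
            model = TitrationModel(
                conformers=tuple((float(w), float(p)) for w, p in entry["conformers"]),
                **kwargs,
            )
            residues.append((str(entry["label"]), model))
        return cls(
            residues=residues,
            pH_grid=tuple(raw.get("pH_grid", tuple(range(1, 9)))),
            n_monomers=int(raw.get("n_monomers", 3)),
            n_replicas=int(raw.get("n_replicas", 3)),
            duration=float(raw.get("duration", 200.0)),
            seed=int(raw.get("seed", 0)),
        )


def sub_seed(master_seed: int, residue: str, monomer: int, replica: int, pH: float) -> int:
    """Stable per-file seed derived from the master seed and file indices."""
    entropy = [
        int(master_seed) & 0xFFFFFFFF,
        zlib.crc32(residue.encode()),
        int(monomer),
        int(replica),
        int(round(pH * 1000)),
    ]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


def generate_dataset(spec: PanelSpec, out_dir, overwrite: bool = False) -> dict:
    """Write one xvg per (residue, monomer, replica, pH) plus a JSON manifest.

    The manifest records every file, its derived sub-seed, and the true
    model parameters — the recovery target for downstream validation.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise DataError(f"output directory {out_dir} is not empty (use overwrite)")
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for label, model in spec.residues:
        res_dir = out_dir / label
        res_dir.mkdir(exist_ok=True)
        for m in range(spec.n_monomers):
            for r in range(spec.n_replicas):
                for pH in spec.pH_grid:
                    seed = sub_seed(spec.seed, label, m, r, pH)
                    traj = simulate_lambda(
                        model, pH, spec.duration, seed,
                        residue_id=label, monomer=m, replica=r,
                    )
                    rel = f"{label}/m{m}_r{r}_pH{pH:g}.xvg"
                    write_lambda_xvg(traj, out_dir / rel)
                    entries.append({
                        "residue": label, "monomer": m, "replica": r,
                        "pH": pH, "file": rel, "sub_seed": seed,
                    })
    manifest = {
        "seed": spec.seed,
        "pH_grid": list(spec.pH_grid),
        "n_monomers": spec.n_monomers,
        "n_replicas": spec.n_replicas,
        "duration": spec.duration,
        "models": {
            label: {
                "conformers": [list(c) for c in model.conformers],
                "exchange_time": model.exchange_time,
                "proto_relax_time": model.proto_relax_time,
                "emission_sd": model.emission_sd,
                "frame_interval": model.frame_interval,
            }
            for label, model in spec.residues
        },
        "files": entries,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
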