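"""Construct tests/data/synthetic_s1_pka_table.csv.

The per-residue supplementary pKa table behind the published cross-method
benchmark is distributed as a spreadsheet and is not reproduced here.  This
script builds a SYNTHETIC stand-in with the same structure (41 acidic
residues × 7 methods, censored cells for residues that never titrate inside
pH 1-8) whose summary statistics over the 31 jointly usable residues equal
the published values:

    RMSD vs CpHMD:  PROPKA 1.19, DeepKa 0.99, PB_A 1.70, H++ 1.32,
                    KaML-CBT 0.92, KaML-ESM 1.35
    pairwise:       PB_A vs H++ 1.40, PROPKA vs DeepKa 0.80

The ten censored rows contain the published anomalous-ionization entries
plus two synthetic ones; all other residue labels and values are synthetic
(drawn, then deterministically adjusted so the statistics above hold
exactly).  Residues named in the main text keep their quoted CpHMD values
(D107 1.5, D121 1.3, D97 3.0, E2 3.6).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

HERE = Path(__file__).resolve().parent
OUT = HERE.parent / "tests" / "data" / "synthetic_s1_pka_table.csv"

METHODS = ["CpHMD", "PROPKA", "DeepKa", "PB_A", "H++", "KaML-CBT", "KaML-ESM"]

# published anomalous rows (CpHMD censored), first five columns as printed;
# KaML columns synthesized (these rows never enter the benchmark statistics)
TABLE2 = [
    ("D37", "< 1", "4.9", "3", "0.3", "2.9", "3.4", "3.1"),
    ("E62", "< 1", "2.5", "2.6", "0.4", "< 0", "2.8", "3.0"),
    ("E71", "< 1", "1.1", "4.1", "0.5", "4.6", "3.6", "3.9"),
    ("D126", "< 1", "3.2", "2.5", "0.5", "< 0", "2.6", "2.9"),
    ("D127", "> 8", "7.4", "5.5", "3.8", "6.6", "5.9", "6.1"),
    ("D256", "> 8", "6", "3.2", "0.6", "< 0", "3.9", "4.2"),
    ("E296", "> 8", "9.6", "7.3", "8.9", "9.4", "7.8", "8.1"),
    ("D312", "> 8", "4.5", "6.5", "1.5", "4.0", "5.6", "5.2"),
]
# two fully synthetic censored rows, bringing the excluded set to ten so the
# usable benchmark set has the published size of 31
EXTRA_CENSORED = [
    ("D44", "< 1", "2.9", "2.2", "0.8", "1.9", "2.4", "2.7"),
    ("E48", "> 8", "7.9", "6.8", "7.2", "8.3", "7.1", "7.5"),
]

# 31 numeric residues: labels named in the text keep their quoted CpHMD pKa
FIXED_CPHMD = {"E2": 3.6, "D97": 3.0, "D107": 1.5, "D121": 1.3, "E117": 6.3}
ASP_LABELS = [
    "D97", "D107", "D113", "D121", "D172", "D330",
    "D12", "D54", "D74", "D84", "D92", "D102", "D115", "D137", "D149",
    "D158", "D183", "D195", "D206", "D221", "D239",
]
GLU_LABELS = ["E2", "E117", "E233", "E29", "E51", "E98", "E146", "E183x", "E200", "E284"]
GLU_LABELS = [lab if lab != "E183x" else "E184" for lab in GLU_LABELS]

RMSD_REF = {"PROPKA": 1.19, "DeepKa": 0.99, "PB_A": 1.70, "H++": 1.32,
            "KaML-CBT": 0.92, "KaML-ESM": 1.35}
PAIRS = [("PB_A", "H++", 1.40), ("PROPKA", "DeepKa", 0.80)]


def _set_norm(v: np.ndarray, target: float) -> np.ndarray:
    return v * (target / np.linalg.norm(v))


def _set_pair(a: np.ndarray, b: np.ndarray, dist: float) -> np.ndarray:
    """Rotate/scale b in span(a, b) so that |a-b| = dist, keeping |b|."""
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    cos_t = (na**2 + nb**2 - dist**2) / (2 * na * nb)
    if not -1 < cos_t < 1:
        raise ValueError("pair distance incompatible with norms")
    ua = a / na
    perp = b - (b @ ua) * ua
    uperp = perp / np.linalg.norm(perp)
    return nb * (cos_t * ua + np.sqrt(1 - cos_t**2) * uperp)


def main() -> None:
    rng = np.random.default_rng(20240917)
    labels = ASP_LABELS + GLU_LABELS
    assert len(labels) == 31 and len(set(labels)) == 31
    n = len(labels)
    cphmd = rng.uniform(1.6, 5.6, n)
    # two thirds of the shifts negative, as in the published panel
    for lab, val in FIXED_CPHMD.items():
        cphmd[labels.index(lab)] = val

    sqn = np.sqrt(n)
    resid = {m: rng.standard_normal(n) for m in RMSD_REF}
    for m, r in RMSD_REF.items():
        resid[m] = _set_norm(resid[m], sqn * r)
    for ma, mb, dist in PAIRS:
        resid[mb] = _set_pair(resid[ma], resid[mb], sqn * dist)
        resid[mb] = _set_norm(resid[mb], sqn * RMSD_REF[mb])  # no-op, safety

    values = {m: np.round(cphmd + resid[m], 3) for m in RMSD_REF}
    cphmd = np.round(cphmd, 3)

    # verify the statistics survive rounding at the printed precision
    def rmsd(a, b):
        return float(np.sqrt(np.mean((a - b) ** 2)))

    for m, target in RMSD_REF.items():
        got = rmsd(values[m], cphmd)
        assert abs(got - target) < 5e-3, (m, got, target)
    for ma, mb, dist in PAIRS:
        got = rmsd(values[ma], values[mb])
        assert abs(got - dist) < 5e-3, (ma, mb, got, dist)

    rows = []
    for row in TABLE2 + EXTRA_CENSORED:
        rows.append(",".join(row[:1] + tuple(row[1:])))
    for i, lab in enumerate(labels):
        cells = [lab, f"{cphmd[i]:.3f}"]
        cells += [f"{values[m][i]:.3f}" for m in METHODS[1:]]
        rows.append(",".join(cells))

    OUT.parent.mkdir(parents=True, exist_ok=True)
    with open(OUT, "w") as fh:
        fh.write("# SYNTHETIC stand-in for the supplementary per-residue pKa table:\n")
        fh.write("# labels/values invented except the published anomalous rows and\n")
        fh.write("# quoted CpHMD values; built so benchmark RMSDs over the 31 usable\n")
        fh.write("# residues match the published summary statistics. See the script\n")
        fh.write("# scripts/make_synthetic_pka_fixture.py.\n")
        fh.write("residue," + ",".join(METHODS) + "\n")
        fh.write("\n".join(rows) + "\n")
    print(f"wrote {OUT} ({len(rows)} residues)")


if __name__ == "__main__":
    main()
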