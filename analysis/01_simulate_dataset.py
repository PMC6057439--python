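"""Generate the synthetic fascicle study.

Emulates the deposited age-series design: 8 age groups (1.6-35.3 months)
with 3-4 mice each and two fascicle segments (technical replicates) per
mouse for tensile testing; per-group fibril-diameter populations drawn from
two-Gaussian mixtures at the published descriptive scales; and packed-disc
micrograph fields with known area fraction.  Ground truth is written beside
every artifact so the downstream drivers can score recovery.

Writes results/synthetic/: mtt traces + truth JSONs, diameters.csv,
mixture_truth.csv, field CSVs.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from tendonmech import io, simulate

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "synthetic"

#: per-age-group study conditions: number of mice, group-mean stiffness and
#: strength (MPa), and the diameter-subpopulation means/SDs (nm) at the
#: scales reported for aged mouse tail tendon
GROUPS = {
    #        mice   E      sU     D1   sd1  D2   sd2   rho
    "01M": dict(n=3, E=376.9, sU=26.6, mu1=104, sd1=32, mu2=178, sd2=68, rho=0.56),
    "02M": dict(n=3, E=574.4, sU=42.6, mu1=106, sd1=40, mu2=201, sd2=46, rho=0.79),
    "04M": dict(n=3, E=619.8, sU=58.6, mu1=260, sd1=60, mu2=340, sd2=20, rho=0.85),
    "11M": dict(n=4, E=626.2, sU=62.4, mu1=111, sd1=30, mu2=250, sd2=50, rho=0.78),
    "23M": dict(n=3, E=566.2, sU=58.6, mu1=65, sd1=22, mu2=240, sd2=61, rho=0.76),
    "29M": dict(n=4, E=624.4, sU=60.3, mu1=56, sd1=9, mu2=220, sd2=82, rho=0.81),
    "31M": dict(n=4, E=575.8, sU=51.6, mu1=50, sd1=12, mu2=230, sd2=85, rho=0.78),
    "35M": dict(n=4, E=465.2, sU=45.6, mu1=42, sd1=9, mu2=214, sd2=78, rho=0.76),
}

SEGMENTS = 2          # fascicle segments per mouse
FIELDS_PER_GROUP = 2
FIELD_RHO = 0.45      # attainable by sequential random disc placement


#: between-mouse coefficient of variation of stiffness and strength
MOUSE_CV = 0.08


def trace_params(g: dict, seed: int, scale: float) -> simulate.TraceParams:
    # individual curves must satisfy E >= sigma_U / eps_U; anchor the peak
    # strain so the secant slope is half the tangent stiffness
    E, sU = g["E"] * scale, g["sU"] * scale
    epsU = 2.0 * sU / E
    return simulate.TraceParams(
        E_true=E, sigmaU_true=sU,
        epsY_true=0.55 * epsU, epsU_true=epsU, rupture_eps=1.4 * epsU,
        seed=seed)


def main() -> int:
    OUT.mkdir(parents=True, exist_ok=True)
    seed_root = np.random.SeedSequence(20260928)
    truth_rows = []
    n_traces = 0
    mouse_rng = np.random.default_rng(seed_root.spawn(1)[0])
    for gi, (group, g) in enumerate(GROUPS.items()):
        for mouse in range(1, g["n"] + 1):
            scale = float(np.exp(mouse_rng.normal(0.0, MOUSE_CV)))
            for seg in "ab":
                sid = f"mtt{group[:2]}_{mouse}_t1{seg}"
                seed = int(1000 * gi + 10 * mouse + ord(seg))
                trace, truth = simulate.simulate_trace(
                    trace_params(g, seed, scale), specimen_id=sid)
                io.write_mtt_trace(trace, OUT / f"{sid}.txt")
                truth_rows.append({"specimen": sid, "age_group": group,
                                   "sample": mouse,
                                   **{k: getattr(truth, k) for k in
                                      ("E", "sigma_Y", "sigma_U", "u_0")}})
                n_traces += 1
    pd.DataFrame(truth_rows).to_csv(OUT / "trace_truth.csv", index=False)

    dia_frames = []
    for gi, (group, g) in enumerate(GROUPS.items()):
        p = simulate.MixtureParams(mu1=g["mu1"], mu2=g["mu2"],
                                   sd1=g["sd1"], sd2=g["sd2"],
                                   weight1=0.5, n=2000, seed=7000 + gi)
        d, _ = simulate.simulate_diameters(p)
        dia_frames.append(pd.DataFrame({"group": group, "D_nm": d}))
    pd.concat(dia_frames).to_csv(OUT / "diameters.csv", index=False)
    pd.DataFrame([{"group": k, **{x: v[x] for x in
                                  ("mu1", "sd1", "mu2", "sd2")}}
                  for k, v in GROUPS.items()]).to_csv(
        OUT / "mixture_truth.csv", index=False)

    field_rows = []
    for gi, group in enumerate(GROUPS):
        for j in range(FIELDS_PER_GROUP):
            rec, rho = simulate.simulate_field(simulate.FieldParams(
                target_rho=FIELD_RHO, seed=100 * gi + j),
                image_id=f"Scan{8 * gi + j + 1:03d}")
            field_rows.append({"group": group, "image_id": rec.image_id,
                               "rho_truth": rho,
                               "n_fibrils": len(rec.fibril_areas)})
            pd.DataFrame({"a_f_nm2": rec.fibril_areas,
                          "interior": rec.interior}).to_csv(
                OUT / f"{rec.image_id}_{group}.csv", index=False)
    pd.DataFrame(field_rows).to_csv(OUT / "field_truth.csv", index=False)

    print(f"wrote {n_traces} traces, {len(GROUPS)} diameter samples and "
          f"{len(field_rows)} disc fields under {OUT}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
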