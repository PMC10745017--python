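"""Calibration diagnostics for the packaged cohort-model constants.

Draws a large cohort from the default (or a supplied) configuration and
prints its marginals next to the calibration targets the defaults were
tuned to.  The packaged constants were fixed once with this script; it is
kept so the tuning is reproducible and so alternative configurations can
be vetted before use.

    python scripts/calibrate_cohort.py [--n 20000] [--seed 1] [--config cfg.json]
"""

import argparse

import numpy as np

from luscab.accuracy import roc_auc
from luscab.records import cohort_to_frame
from luscab.scoring import score_frame
from luscab.simulate import CohortModelConfig, default_paper_config, generate_cohort

TARGETS = {
    "fraction male": 0.60,
    "fraction age < 1 month": 0.22,
    "median age (months)": 2.18,
    "median WDF": 4.5,
    "fraction admitted": 0.66,
    "fraction any oxygen": 0.42,
    "fraction HFNC or higher": 0.36,
    "fraction nCPAP/nBiPAP/MV": 0.16,
    "median LUSCAB": 2.5,
}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--n", type=int, default=20000)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--config", default=None)
    args = ap.parse_args()

    if args.config:
        with open(args.config, encoding="utf-8") as fh:
            cfg = CohortModelConfig.from_json(fh.read())
        cfg = CohortModelConfig(**{**cfg.__dict__, "n": args.n, "seed": args.seed})
    else:
        cfg = default_paper_config(n=args.n, seed=args.seed)

    frame = score_frame(cohort_to_frame(generate_cohort(cfg)))
    age = frame["age_months"].to_numpy()
    wdf = frame["wdf_total"].to_numpy(dtype=float)
    lus = frame["luscab_total"].to_numpy()
    tier = frame["support_tier"]

    achieved = {
        "fraction male": (frame["sex"] == "male").mean(),
        "fraction age < 1 month": (age < 1).mean(),
        "median age (months)": np.median(age),
        "median WDF": np.median(wdf),
        "fraction admitted": frame["admitted"].mean(),
        "fraction any oxygen": frame["oxygen_therapy"].mean(),
        "fraction HFNC or higher": (tier != "none").mean(),
        "fraction nCPAP/nBiPAP/MV": (tier == "ncpap_bipap_mv").mean(),
        "median LUSCAB": np.median(lus),
    }
    print(f"n = {cfg.n}, seed = {cfg.seed}")
    print(f"{'quantity':34s} {'target':>8s} {'achieved':>9s}")
    for k, target in TARGETS.items():
        print(f"{k:34s} {target:8.2f} {achieved[k]:9.3f}")

    print("\nper-tier medians (none / lfnc_hfnc / ncpap_bipap_mv):")
    for var in ("wdf_total", "luscab_total"):
        meds = [frame.loc[tier == t, var].median() for t in ("none", "lfnc_hfnc", "ncpap_bipap_mv")]
        print(f"  {var:14s} " + " / ".join(f"{m:.1f}" for m in meds))
    for name, y in (("nCPAP/nBiPAP/MV", tier == "ncpap_bipap_mv"), ("HFNC or higher", tier != "none")):
        print(f"  AUC {name:16s} {roc_auc(lus, y.to_numpy()).auc:.3f}")


if __name__ == "__main__":
    main()
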