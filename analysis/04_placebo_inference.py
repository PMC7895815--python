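"""Placebo-based inference for the synthetic control analysis.

Three robustness stages on the simulated panel, mirroring the main fit in
03_synthetic_control.py:

* placebo-in-space — every donor treated in turn, post/pre-MSPE ratios,
  the treated unit's rank-based permutation p-value, and the 5x-MSPE
  filtered gap comparison;
* placebo-in-time — dummy intervention dates 1995-1998;
* leave-one-out — iterative removal of the top-weighted donor.

Since the panel is a null world, the expected findings are an unremarkable
treated rank (p well away from 1/16) and time-placebo fits that stay close
to the main fit.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from itsynth import (AnalysisWindow, filter_placebos, leave_one_out,
                     mspe_ratio_test, placebo_in_space, read_panel,
                     search_groupings, time_placebo)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--panel", type=Path,
                    default=ROOT / "panels" / "sc_panel.csv")
    ap.add_argument("--out", type=Path, default=ROOT / "placebo")
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    panel = read_panel(args.panel)
    treated = "England and Wales"
    donors = [c for c in panel.countries if c != treated]
    window = AnalysisWindow(1990, 1999, 2013)
    spec = search_groupings(panel, treated, donors, window,
                            seed=args.seed).spec

    pset = placebo_in_space(panel, treated, donors, window, spec=spec,
                            protocol="full", seed=args.seed)
    test = mspe_ratio_test(pset)
    kept = filter_placebos(pset, multiple=5.0)
    pd.DataFrame({
        "unit": list(test.ratios),
        "mspe_pre": [pset.fits[u].mspe_pre for u in test.ratios],
        "ratio": list(test.ratios.values()),
        "retained_after_filter": [u in kept.fits for u in test.ratios],
    }).to_csv(args.out / "ratios.csv", index=False)
    pd.DataFrame({u: f.gaps for u, f in pset.fits.items()}
                 ).rename_axis("year").to_csv(args.out / "gaps_by_unit.csv")
    (args.out / "ratio_test.json").write_text(json.dumps(
        {"treated_ratio": test.ratios[treated],
         "treated_rank": test.treated_rank,
         "n_units": len(test.ratios), "p": test.p,
         "p_display": test.p_display}, indent=2))
    n_exceed = test.treated_rank - 1
    print(f"in-space: treated ratio {test.ratios[treated]:.2f}; "
          f"{n_exceed} of {len(test.ratios) - 1} placebos larger; "
          f"rank {test.treated_rank}/{len(test.ratios)}, "
          f"p = {test.p_display:.2f}; "
          f"{sum(1 for u in kept.fits if u != treated)} placebos within "
          f"5x treated pre-MSPE")

    fits = time_placebo(panel, treated, donors, window,
                        dummy_years=(1995, 1996, 1997, 1998), spec=spec,
                        protocol="full", seed=args.seed)
    pd.DataFrame({d: f.gaps for d, f in fits.items()}
                 ).rename_axis("year").to_csv(
        args.out / "time_placebo_gaps.csv")
    for d, f in fits.items():
        post = f.gaps[f.gaps.index >= d]
        print(f"in-time dummy {d}: mean post-dummy gap {post.mean():+.2f} "
              f"per 1000 women")

    table = leave_one_out(panel, treated, donors, window, spec,
                          max_iter=4, seed=args.seed)
    out = table.copy()
    out["weights"] = out["weights"].map(json.dumps)
    out.to_csv(args.out / "leave_one_out.csv", index=False)
    seq = [d for d in table["dropped"] if d]
    print(f"leave-one-out drop sequence: {' -> '.join(seq)}; "
          f"pre-MSPE {table['mspe_pre'].iloc[0]:.3f} -> "
          f"{table['mspe_pre'].iloc[-1]:.3f}")


if __name__ == "__main__":
    main()
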