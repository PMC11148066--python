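"""Root-hair growth response to sucrose, on synthetic time-lapses.

Simulates the control and sucrose growth regimes (0.75 vs 1.14 µm/min mean
rate, 2.2 vs 3.5 h mean duration), runs tip tracking and kinetics
extraction, and reports per-condition means, fold changes and the Dunn
group comparison. Writes kinetics.csv, summary.csv and comparison.json
under results/hair_growth/.

Run with a smaller --n-hairs for a quick look; the full-scale recovery
(200 hairs per condition) is what scripts/acceptance.py recomputes.
"""

import argparse
import json
import warnings
from pathlib import Path

warnings.filterwarnings("ignore")

from rootlapse.experiments import run_hair_study
from rootlapse.stats import compare_groups
from rootlapse import io as rio


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-hairs", type=int, default=60, help="hairs per condition")
    ap.add_argument("--out", type=Path, default=Path("results/hair_growth"))
    args = ap.parse_args()

    study = run_hair_study(seed=args.seed, n_hairs_per_group=args.n_hairs)
    records, summary = study["records"], study["summary"]
    out = args.out
    out.mkdir(parents=True, exist_ok=True)
    rio.write_table(records, out / "kinetics.csv")
    rio.write_table(summary, out / "summary.csv")

    ok = records[(~records.truncated) & (records.qc == "ok")]
    comparison = {}
    for metric in ("final_length_um", "growth_rate_um_per_min", "duration_h"):
        res = compare_groups(ok, metric, alpha=0.01)
        comparison[metric] = {
            "kruskal_p": res["kruskal_p"],
            "letters": res["letters"],
        }
    (out / "comparison.json").write_text(json.dumps(comparison, indent=2))

    print(f"{len(ok)} usable kinetics records "
          f"({len(records) - len(ok)} truncated/flagged excluded)")
    for _, row in summary.iterrows():
        fold = f"  fold {row.fold_change:.2f}" if row.get("fold_change") == row.get("fold_change") else ""
        print(f"  {row.group:8s} {row.metric:24s} {row['mean']:8.2f} "
              f"+/- {row.se:5.2f} (n={row.n}){fold}")
    for metric, res in comparison.items():
        print(f"  Dunn letters for {metric}: {res['letters']} "
              f"(Kruskal-Wallis p={res['kruskal_p']:.2e})")
    print(f"tables written to {out}")


if __name__ == "__main__":
    main()
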