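"""Stage 2 — serving-substitution models.

Derives the non-dairy remainder of the 2000-kcal reference pattern and
applies the seven substitution plans: Model 1 swaps all three dairy
servings for the updated fat-free composite; Models 2-7 swap one of those
three servings for the reduced-fat composite, the whole-fat composite, or
a single milk/cheese (single foods use shipped synthetic stand-ins, so
Models 4-7 illustrate the mechanics rather than reproduce printed values).

Writes results/model_totals.csv, results/percent_change.csv,
results/run_report.json via the pipeline.
"""
import argparse
from pathlib import Path

from dairypattern.pipeline import RunConfig, run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    report = run_pipeline(RunConfig(out_dir=args.out_dir))
    totals = report["unrounded_totals"]
    base = totals["Model 1"]["amounts"]
    print("day-level energy and sodium by model (vs Model 1 baseline):")
    for name in sorted(totals):
        a = totals[name]["amounts"]
        print(
            f"  {name}: {a['energy']:7.1f} kcal ({a['energy']-base['energy']:+5.1f}), "
            f"sodium {a['sodium']:6.1f} mg ({a['sodium']-base['sodium']:+7.1f})"
        )
    print(
        "\nmodels exceeding the 2300 mg/d sodium CDRR: "
        + ", ".join(report["models_exceeding_sodium_cdrr"])
    )
    print(f"tables -> {args.out_dir}/model_totals.csv, percent_change.csv")


if __name__ == "__main__":
    main()
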