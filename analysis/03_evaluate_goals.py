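"""Stage 3 — dietary-goal evaluation.

Scores each model's day-level profile against the DRI goal table for the
two sample age-sex groups (females 19-30, males 51+): % RDA/AI/UL per
nutrient, macronutrient % of energy, and the saturated-fat (10% of kcal)
and sodium (2300 mg/d CDRR) screens.

Writes results/goal_report.csv and prints the threshold summary.
"""
import argparse
import json
from pathlib import Path

from dairypattern.goals import check_thresholds
from dairypattern.modeling import run_models, shipped_plans
from dairypattern.synth import synthetic_standin_foods


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    from dairypattern.goals import goal_report
    import pandas as pd

    models, _ = run_models(plans=shipped_plans(synthetic_standin_foods()))
    frames = []
    summary = {}
    print("threshold screen (saturated fat display %kcal / sodium mg):")
    for name in sorted(models):
        total = models[name].total
        g = goal_report(total)
        g.insert(0, "model", name)
        frames.append(g)
        flags = check_thresholds(total)
        verdict = (
            "exceeds 10%" if flags.saturated_fat_exceeds
            else "at 10% limit" if flags.saturated_fat_at_limit
            else "within 10%"
        )
        sodium_verdict = "exceeds CDRR" if flags.sodium_exceeds_cdrr else "below CDRR"
        print(
            f"  {name}: satfat {flags.saturated_fat_pct_display:.0f}% ({verdict}), "
            f"sodium {flags.sodium_mg:.0f} mg ({sodium_verdict})"
        )
        summary[name] = {
            "saturated_fat_pct_display": flags.saturated_fat_pct_display,
            "sodium_mg": flags.sodium_mg,
            "sodium_exceeds_cdrr": flags.sodium_exceeds_cdrr,
        }
    pd.concat(frames, ignore_index=True).to_csv(
        args.out_dir / "goal_report.csv", index=False
    )
    (args.out_dir / "thresholds.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(f"goal grid -> {args.out_dir/'goal_report.csv'}")


if __name__ == "__main__":
    main()
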