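"""Stage 1 — dairy composites.

Loads the printed per-serving composite profiles (the 2015-era fat-free
reference composite and the updated fat-free / reduced-fat / whole-fat
composites built from 47.76% milk + 47.30% cheese + 4.93% yogurt intake
shares), prints their normalized weights, and demonstrates the
consumption-weighted construction itself on a seeded synthetic food table.

Writes results/composites.csv (per-serving profiles, printed precision).
"""
import argparse
from pathlib import Path

import pandas as pd

from dairypattern.composites import build_composite, composite_from_table1
from dairypattern.panel import round_for_display
from dairypattern.synth import (
    SyntheticConfig,
    generate_consumption_shares,
    generate_food_table,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    frames = {}
    for name in ("USDA2015", "A", "B", "C"):
        comp = composite_from_table1(name)
        frames[name] = round_for_display(comp.per_serving).set_index("nutrient_id")["value"]
        if comp.normalized_weights:
            shares = ", ".join(
                f"{code}={frac:.4f}" for code, frac in comp.normalized_weights.items()
            )
            print(f"Composite {name}: normalized shares {shares}")
    table = pd.DataFrame(frames)
    table.to_csv(args.out_dir / "composites.csv")
    print(f"\nper-serving composite profiles -> {args.out_dir/'composites.csv'}")
    print(
        "energy per cup-equivalent: "
        + ", ".join(f"{n}={table.loc['energy', n]:.0f} kcal" for n in table.columns)
    )

    # demonstrate the weighted-average construction on synthetic records
    cfg = SyntheticConfig(seed=args.seed, n_foods_per_group=3)
    foods = generate_food_table(cfg)
    spec = generate_consumption_shares(cfg, foods, fat_tier="fat_free")
    demo = build_composite(spec, foods)
    print(
        f"\nsynthetic demo (seed {args.seed}): composite over "
        f"{len(spec.components)} foods, energy "
        f"{demo.per_serving['energy']:.0f} kcal/serving, calcium "
        f"{demo.per_serving['calcium']:.0f} mg/serving"
    )


if __name__ == "__main__":
    main()
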