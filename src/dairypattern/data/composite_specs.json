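{
  "schema_version": 1,
  "note": "Consumption shares for the 2013-2016 updated composites; raw weights sum to 99.99 and are normalized to total 100% by the builder. The 2009-2010 era composite shares are recorded for reference only and are unused in computation (its soymilk component has no food record).",
  "updated_shares": {
    "milk": 47.76,
    "cheese": 47.30,
    "yogurt": 4.93
  },
  "legacy_2009_2010_shares": {
    "milk": 51.0,
    "cheese": 44.8,
    "yogurt": 2.6,
    "soymilk": 1.5
  },
  "composites": {
    "A": {
      "label": "fat-free dairy composite",
      "components": [
        {"food_code": "11113000", "description": "Fat-free milk", "group": "milk", "fat_tier": "fat_free", "weight_percent": 47.76},
        {"food_code": "14410130", "description": "Fat-free cheese", "group": "cheese", "fat_tier": "fat_free", "weight_percent": 47.30},
        {"food_code": "11411300", "description": "Fat-free yogurt", "group": "yogurt", "fat_tier": "fat_free", "weight_percent": 4.93}
      ]
    },
    "B": {
      "label": "reduced-fat dairy composite",
      "components": [
        {"food_code": "11112110", "description": "Reduced-fat milk", "group": "milk", "fat_tier": "reduced_fat", "weight_percent": 47.76},
        {"food_code": "14410120", "description": "Reduced-fat cheese", "group": "cheese", "fat_tier": "reduced_fat", "weight_percent": 47.30},
        {"food_code": "11411200", "description": "Low-fat yogurt (no reduced-fat yogurt exists in the food database)", "group": "yogurt", "fat_tier": "low_fat", "weight_percent": 4.93}
      ]
    },
    "C": {
      "label": "whole-fat dairy composite",
      "components": [
        {"food_code": "11111000", "description": "Whole-fat milk", "group": "milk", "fat_tier": "whole", "weight_percent": 47.76},
        {"food_code": "14410110", "description": "Whole-fat cheese", "group": "cheese", "fat_tier": "whole", "weight_percent": 47.30},
        {"food_code": "11411000", "description": "Whole-fat yogurt (source prints 7-digit code 1141100; stored as the likely 8-digit code)", "group": "yogurt", "fat_tier": "whole", "weight_percent": 4.93}
      ]
    }
  },
  "typo_flags": [
    {"table": "model_tables", "column": "model4_pct", "nutrient_id": "vitamin_a", "printed": "30", "suspected": "3.0", "reason": "inconsistent with neighboring magnitudes"},
    {"table": "model_tables", "column": "model7_pct", "nutrient_id": "energy", "printed": "27", "suspected": "2.7", "reason": "inconsistent with neighboring magnitudes; prose states a 2.7% increase"}
  ]
}
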