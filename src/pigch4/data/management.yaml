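# Animal, barn and management characteristics per pig category, plus the
# outdoor storage tank.  Growing categories (weaned, grower_finisher) are fed
# per batch cycle; sow categories per feed-unit stages over feeding days/year.
# Growing-pig gain and feed-efficiency values are calibration fixtures chosen
# to reproduce typical Danish production figures; they are editable.
categories:
  weaned:
    category: weaned
    body_weight: 18.9          # kg
    manure_temp_barn: 22.0     # deg C
    removal_interval: 27       # days between pit emptyings
    floor_area: 0.3            # m2 per animal place
    pit_area: 0.18             # m2 per animal place
    cycle_period: 59           # days
    empty_days: 5              # days per cycle the section is empty
    wash_water: 15.0           # kg per animal place per cycle
    urine_per_dmi: 2.0         # kg urine per kg DM intake
    intake:
      gain_per_cycle: 21.0     # kg gain per batch cycle (9 -> 30 kg)
      feed_efficiency: 2.09    # FU per kg gain
      cycle_days: 54
  grower_finisher:
    category: grower_finisher
    body_weight: 73.0
    manure_temp_barn: 18.6
    removal_interval: 7
    floor_area: 0.65
    pit_area: 0.715
    cycle_period: 89
    empty_days: 5
    wash_water: 75.0
    urine_per_dmi: 2.0
    intake:
      gain_per_cycle: 84.0     # kg gain per batch cycle (31 -> 115 kg)
      feed_efficiency: 2.648   # FU per kg gain
      cycle_days: 84
  gestating_sow:
    category: gestating_sow
    body_weight: 245.0
    manure_temp_barn: 18.6
    removal_interval: 30
    floor_area: 2.14
    pit_area: 1.05
    cycle_period: 119
    empty_days: 0
    wash_water: 0.0
    urine_per_dmi: 2.5
    intake:
      fu_stages: [104.0, 58.8, 208.0, 582.0, 20.4]   # FU/year/sow
      feeding_days: 285
  lactating_sow:
    category: lactating_sow
    body_weight: 245.0
    manure_temp_barn: 20.0
    removal_interval: 36
    floor_area: 4.9
    pit_area: 2.94
    cycle_period: 40
    empty_days: 4
    wash_water: 340.0
    urine_per_dmi: 2.5
    intake:
      fu_stages: [39.1, 499.3]   # FU/year/sow
      feeding_days: 80
storage:
  height: 5.5                  # m
  diameter: 36.0               # m
  covered: true
  removal_schedule:            # day-of-year, fraction of mass removed
    - [105, 0.80]              # spring application
    - [288, 0.20]              # autumn application
  monthly_temps: [2.9, 3.1, 5.0, 8.2, 12.0, 15.5, 17.8, 17.5, 14.8, 10.9, 6.8, 3.9]
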