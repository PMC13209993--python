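# dqscore

A food-based **Diet Quality Score (DQS)** measuring how closely dietary
intake aligns with the Australian Dietary Guidelines-2013, together with the
processing chain that turns analyst-coded food records into scoreable
intakes, a misreporting screen, and the statistics used to establish a diet
quality index's construct validity.

The package is for nutrition and epidemiology researchers who have
food-level intake records (for example from image-based dietary assessment,
where items are identified and weighed but nutrient panels are not needed)
and want a guideline-alignment score plus the standard validation analyses
around it.

## The score

Eleven components are scored from mean daily intake and summed to a 0–100
total. Nine components are worth 0–10 points and two (fruit and vegetable
variety) 0–5 points:

* **Adequacy** — fruit, vegetables, fruit variety, vegetable variety,
  milk/alternatives, plain water: more is better, with maximum points at or
  above the recommended daily serves (e.g. fruit ≥ 2 serves/day → 10).
* **Optimal range** — grain (cereal) foods and lean meat/alternatives:
  maximum points only at the recommended amount (grain 6.0 serves; meat 2.5
  serves for women, 3.0 for men), zero both below the minimum and above the
  range.
* **Moderation** — discretionary foods, sugar-sweetened beverages, alcohol:
  reverse-scored, with zero consumption earning 10 points.

Intake preparation follows the food-based approach: each consumed item is
disaggregated into core food-group serves via its per-100 g serve content
(a chicken-and-salad sandwich contributes grain, vegetable and meat serves
simultaneously); items flagged discretionary/SSB/alcohol are excluded from
core serves and instead scored by energy at 600 kJ = 1 serve; water is
counted in 250 mL cups; every total is divided by the number of recorded
days. Participants with fewer than 2 recorded days are excluded, and the
EI:BMR misreporting screen (Schofield weight-only BMR; top and bottom 2.5%
of the energy-intake:BMR distribution trimmed by rank) runs before any
scoring-based analysis.

## Worked example

`examples/01_score_a_record.py` scores a 4-day record against a small
composition table:

```
days recorded:        4
  grain                4.200 serves/day
  fruit                1.200 serves/day
  vegetable            1.000 serves/day
  ...
  water                5.00 cups/day

component points (0-10, varieties 0-5):
  fruit                5
  vegetable            2
  ...
  discretionary_food   4
  ssb                  8
  alcohol              10

DQS total: 53 / 100
```

1.2 fruit serves/day falls in the ≥1.0–<1.5 band (5 points); 4.2 grain
serves in ≥4–<5 (6 points); roughly one discretionary serve per day (600 kJ
of pie energy) lands in the ≥0.75–<1.75 moderation band (4 points). The
total of 53/100 indicates moderate guideline alignment.

The other examples cover the misreporting screen
(`02_misreporting_screen.py`), the full pipeline on a synthetic
280-participant cohort (`03_full_pipeline.py` — flow 280 → 272 → 260 after
the day filter and tail screen), and the construct-validity battery with a
comparator index (`04_construct_validity.py`).

A thin CLI wraps the same library:

```bash
dqscore simulate --seed 7 --out fixture/
dqscore run --composition fixture/composition.csv --intake fixture/intake.csv \
            --participants fixture/participants.csv --out results/
```

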