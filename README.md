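# fishhealth

Analysis toolkit for seasonal fish-health surveys in mercury-impacted
tropical floodplains: fish condition indices, nematode parasitology,
mercury measurement QC, USEPA-style consumption-risk screening, an
assumption-gated statistical battery, liver histopathology clustering, and
distance-based phylogenetics for parasite barcode sequences.

It is written for ecotoxicologists and fish-health researchers who sample a
set of species across hydrological seasons (a species × season design),
measure muscle total mercury (T-Hg), count larval nematodes, and want the
full downstream analysis to be scripted, tested and reproducible. Because
raw survey tables of this kind are rarely deposited, the package ships a
calibrated synthetic cohort generator that emulates a nine-species,
two-season survey (326 specimens) so every stage can be exercised end to
end without field data.

## What it computes

**Condition indices.** Fulton's condition factor CF = 100·W/L³ and the
hepatosomatic index HSI = 100·LW/W per fish, summarised as mean ± SE per
species × season stratum.

**Parasitology.** Prevalence P = infected/examined, mean abundance
A = parasites/examined and mean intensity I = parasites/infected per
stratum, with the exact identity A = P·I, and two-sided Fisher exact tests
for seasonal prevalence contrasts.

**Mercury QC.** Detection limit LOD = 3·sd(blanks), replicate precision
(RSD < 10%), calibration linearity (R² ≥ 0.999) and certified reference
material recovery, with below-LOD substitution at LOD/2.

**Risk screening.** With C = 0.9·T-Hg (the methylmercury fraction),
meal size MS (g) and body weight BW (kg):

    EDI  = C·MS/BW            (µg/kg/day)
    HQ   = EDI/RfD            (RfD = 0.1 µg/kg/day)
    CRmw = 7·RfD·BW/(C·MS)    (meals/week; 49/(C·MS) for a 70-kg adult)

HQ > 1 flags potential non-cancer risk; CRmw is floored to whole meals.

**Statistics.** Normality (Kolmogorov–Smirnov) and homogeneity (Bartlett)
gates dispatching t/Mann–Whitney and ANOVA/Kruskal–Wallis; Spearman and
partial Spearman correlation; PCA on the correlation matrix; backward
model selection by AIC over OLS fits.

**Histopathology.** Ten lesion categories scored 0–3 per liver, occurrence
rates, severity bins (absent/mild/moderate/severe) and Euclidean-distance
hierarchical clustering for heatmaps.

**Phylogenetics.** Pairwise identity and p-distance with pairwise gap/N
deletion, Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3), Saitou–Nei
neighbor joining, and column-bootstrap supports.

## Worked example

```python
from fishhealth import GeneratorConfig, generate_cohort, assess_cohort
from fishhealth.parasitology import summarize_parasitology

cohort = generate_cohort(GeneratorConfig(seed=1))
overall = summarize_parasitology(cohort)[-1]
print(f"n = {len(cohort)}, prevalence = {overall.prevalence:.2f}, "
      f"abundance = {overall.mean_abundance:.2f}")

adult = [r for r in assess_cohort(cohort) if r.profile == "adult"]
worst = max(adult, key=lambda r: r.hq)
print(f"worst stratum: {worst.species} ({worst.season}), "
      f"HQ = {worst.hq:.1f}, allowed meals/week = {worst.crmw_meals}")
```

prints

```
n = 326, prevalence = 0.50, abundance = 3.32
worst stratum: Cynopotamus magdalenae (dry), HQ = 17.1, allowed meals/week = 0
```

i.e. roughly half the synthetic cohort is infected, and the most
contaminated stratum mean exceeds the reference dose ~17-fold for an adult
eating one standard 230-g meal per day — that stratum should not be eaten
even once a week.

The same analyses are available from the shell:

```
fishhealth generate --seed 1 --out specimens.csv
fishhealth run --seed 1 --out report/        # full bundle: tables + figures
fishhealth risk specimens.csv --out risk.csv
fishhealth phylo alignment.fasta --replicates 1000 --out tree.nwk
```

## Layout

- `src/fishhealth/` — the library (`model`, `io`, `synthetic`, `indices`,
  `parasitology`, `mercury_qc`, `risk`, `stats`, `histology`, `phylo`,
  `pipeline`, `cli`).
- `docs/methods.md` — models, assumptions, calibration and numerical
  choices; `docs/file_formats.md` — the CSV/FASTA/newick column contracts.
- `tests/` — the pytest suite, including oracle-based checks (exact-test
  enumeration, additive-matrix NJ recovery, closed-form Jukes–Cantor).
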