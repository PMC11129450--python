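# pgxtraj

Pharmacogenomics of antidepressant treatment trajectories: a tested,
reusable implementation of a longitudinal cohort analysis that asks
whether **CYP2D6** and **CYP2C19** metabolizer phenotypes are associated
with **switching or discontinuing antidepressants**, and with the number
of perceived side effects.

It is aimed at pharmacoepidemiologists and psychiatric-genetics
researchers who want the full analysis chain as a library: star-allele
diplotype → metabolizer phenotype translation, ATC-based substrate
classification, trajectory classification over an 11-period observation
window, ASEC-12 side-effect aggregation, the statistical layer, and a
synthetic cohort generator standing in for the access-restricted study
data.

## The model

* **CYP2D6 phenotype** from the gene dose (activity score)
  `d = d(a₁) + d(a₂)` with d = 1 / 0.5 / 0 for fully functional
  (*1, *2), reduced (*10, *17, *41) and inactive (*3, *4, *6) alleles:
  PM (d = 0), IM (0.5–1), NM (1.5–2.5).
* **CYP2C19 phenotype** from combination rules over *1 (functional),
  *2/*3 (inactive) and *17 (increased): two inactive → PM, one → IM,
  *1/*1 and *1/*17 → NM, *17/*17 → UM; the CPIC convention instead
  classifies *1/*17 as UM.
* **Trajectories**: patients starting a single index antidepressant are
  labelled MAINTAINED / SWITCHED / DISCONTINUED by pairwise comparison of
  successive antidepressant-use periods, where comparisons spanning
  treatment-free gaps supersede consecutive ones and a switch means full
  replacement of the drug set.
* **Association**: crude odds ratios `OR = ad/bc` with Wald intervals
  `exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d))` (equivalently, IRLS logistic
  regression on the collapsed groups NM vs IM/PM, plus UM for CYP2C19),
  Mann–Whitney U for side-effect burdens, and post-hoc power via Cohen's
  `h = 2·asin√p₂ − 2·asin√p₁`.

See `docs/methods.md` for assumptions, parameter defaults and
limitations.

## Worked example

Generate a synthetic cohort at the study's scale (n = 928 patients) and
run the full pipeline:

```bash
pgxtraj generate --out cohort/ --seed 5
pgxtraj run --input-dir cohort/ --output-dir report/
```

The run prints the selection flow and the association tables; with seed 5
the output begins:

```
[flow] genotyped patients: kept 928, excluded 0
[flow] eligible single-AD starters: kept 928, excluded 0
[flow] classifiable trajectories: kept 928, excluded 0

CYP2D6 substrate users (n = 797)
group               maintained        discontinued            switched
IM/PM               60 (45.1%)          20 (15.0%)          53 (39.8%)
NM                 331 (49.8%)          95 (14.3%)         238 (35.8%)

contrast      group           OR            95% CI   power
discontinued  IM/PM         1.16     (0.67 - 2.02)    0.08
switched      IM/PM         1.23     (0.82 - 1.84)    0.17
```

Reading this: of the 928 synthetic patients, 797 started an
antidepressant metabolized by CYP2D6; the odds of discontinuing (vs
maintaining) for IM/PM patients relative to NM patients are 1.16 with a
95% CI of 0.67–2.02 — no association, as expected since the generator's
default injects none — and the post-hoc power of that comparison is 0.08.
`report/` additionally contains `trajectory.csv`,
`association_table.csv`, `side_effects.csv` (Mann–Whitney comparisons per
category), `reasons_table.csv` and a plain-text `report.txt`.

The same analysis is available as a library, statsmodels-style:

```python
from pgxtraj import MetabolizerAssociation

model = MetabolizerAssociation.from_counts(
    {"NM":    {"maintained": 352, "discontinued": 88, "switched": 223},
     "IM/PM": {"maintained": 60,  "discontinued": 22, "switched": 51}},
    enzyme="CYP2D6",
)
print(model.fit().summary())
```

which prints ORs of 1.47 (0.85 – 2.52) for discontinuing and
1.34 (0.89 – 2.02) for switching.

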