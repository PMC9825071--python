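# csurv

A common data model toolkit for population-cohort research data.

Population cohorts (ageing studies, biobanks, disease registers) each evolve
their own variable names, value codings and documentation. Anyone running a
multi-cohort analysis must first rediscover and re-curate each dataset —
slowly, idiosyncratically and per project. `csurv` implements a common data
model that makes cohort data *research-ready*, plus the feasibility tooling
that a common model enables:

* **Taxonomy** — a machine-readable, four-level acyclic hierarchy of research
  phenotypes: *theme* → *domain* → *family* → *object*, where an object is a
  single measured variable. The shipped reference document has 18 themes
  (e.g. Sociodemographic, Cognitive status, Imaging, Molecular); a second
  fixture carries the fully specified 32-object harmonised subset. The tiered
  structure supports both grouped selection ("all processing speed
  variables") and individual variable selection.
* **Naming grammar** — every curated variable name is
  `COHORT_MEASUREMENT[q<item>]_<serial>_<wave>`: a 3-letter cohort code, an
  upper-case measurement abbreviation (≤ 12 characters for survey data, ≤ 17
  for imaging/omics/device data; lower-case reserved for the constant markers
  `q` = question, `r` = range, `d` = decimal point), a serialisation index
  (0 = unrepeated within a data-capture period) and a 1-based study wave.
  `GEN_SPQq1_0_1` is item 1 of the SPQ in Generation Scotland, unrepeated, at
  recruitment. A formally diagnosed measure carries the `DX` suffix
  (`PTSD` vs `PTSDDX`).
* **Value conventions** — missing (absence of recorded data) is a dedicated
  sentinel, serialised as `.`; informative non-response ("don't know",
  "prefer not to answer") stays a value so inclusion decisions can be made
  per hypothesis; gender is coded 2 = female / 1 = male; imperial
  anthropometry converts to metric with exact factors (inch → cm 2.54,
  pound → kg 0.45359237, stone → kg 6.35029318). Native value labels are
  always retained alongside the curated ones.
* **Curation pipeline** — a per-cohort *mapping spec* (YAML/JSON) binds
  native columns to taxonomy objects, canonical names and recode rules;
  `apply_mapping` produces a fully conformant wide table plus a generated
  data dictionary (full question text, units, curated + native labels,
  provenance) and a curation report.
* **Feasibility engine** — availability matrices (participants with data,
  per harmonised variable × cohort) and conjunctive filter funnels
  (sequential counts under e.g. *age ≥ 50*, *never-smoker*, …), per cohort
  and pooled. Only counts leave the API. z-score / min-max standardisation
  supports cross-cohort comparability of scale variables.
* **Synthetic cohorts** — a seeded generator of messy native-style tables
  (snake/camel/cryptic names, imperial units, per-cohort missing codes −9 /
  −99 / blank, labelled non-response, repeated measures across waves) with an
  exact curation ground truth, so the whole pipeline is testable without
  access-controlled data.

## Worked example

```python
from csurv import (
    parse_object_name, reference_taxonomy, count_nodes,
    SynthConfig, default_blueprints, generate_native_cohort,
    apply_mapping, HarmonisedVariable, FilterStep, funnel,
)

name = parse_object_name("GEN_SPQq1_0_1")
print((name.cohort, name.measurement, name.item, name.serial, name.wave))
# ('GEN', 'SPQ', 1, 0, 1)

tax = reference_taxonomy()
print(count_nodes(tax, 1), count_nodes(tax, 4))
# 18 34

# two messy synthetic cohorts, curated with their own truth specs
cohorts = []
for code, seed in (("AAA", 1), ("BBB", 2)):
    cfg = SynthConfig(cohort_code=code, n_participants=2000,
                      variables=default_blueprints(), seed=seed)
    native, manifest = generate_native_cohort(cfg)
    cohorts.append(apply_mapping(native, manifest.spec, tax))
print(cohorts[0].report["variables_mapped"], cohorts[0].report["cells_recoded"])
# 10 6919

age = HarmonisedVariable("Age", {c.cohort_code: f"{c.cohort_code}_AGE_0_1" for c in cohorts})
smk = HarmonisedVariable("Smoking status",
                         {c.cohort_code: f"{c.cohort_code}_SMOKSTAT_0_1" for c in cohorts})
res = funnel(cohorts, [FilterStep(age, "ge", 50), FilterStep(smk, "eq", 0)])
print("base", res.base, res.base_pooled)
for s in res.steps:
    print(s.step.label, s.per_cohort, s.pooled)
# base {'AAA': 2000, 'BBB': 2000} 4000
# Age >= 50 {'AAA': 1829, 'BBB': 1836} 3665
# Smoking status = 0 {'AAA': 560, 'BBB': 527} 1087
```

The funnel reads: of 4,000 pooled participants, 3,665 are aged 50+ and of
those 1,087 are also recorded never-smokers with usable (non-missing) data —
exactly the numbers a data-access request should be planned around. Missing
values fail every predicate (funnels count usable complete data); an
explicit `nonmissing`/`missing` predicate is available for missingness
analysis.

The same pipeline is scriptable from a shell:

```sh
csurv simulate --cohort AAA --n 1000 --seed 5 --out sim/
csurv curate --native sim/native.csv --spec sim/truth_spec.yaml --out curated/
csurv explore --cohorts curated/curated.csv --spec harm.yaml --funnel funnel.yaml
csurv name parse GEN_SPQq1_0_1
csurv validate-taxonomy my_taxonomy.yaml
```

## Layout

```
src/csurv/
  taxonomy.py     four-level hierarchy: load, validate, query
  naming.py       object-name grammar: parse, format, validate
  recode.py       value conventions: missing, non-response, gender, units
  curate.py       mapping specs, curated datasets, data dictionaries
  explorer.py     availability matrices, filter funnels, standardisation
  synthcohort.py  seeded messy-cohort generator with ground truth
  cli.py          `csurv` command-line interface
  data/           reference and harmonised-subset taxonomy documents
  schemas/        JSON-Schema for taxonomy and mapping-spec documents
docs/methods.md   models, conventions and design choices in detail
```
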