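# Methods

This note records the data model the package implements, the conventions and
parameters that matter, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the design was genuinely open.

## The data model

### Taxonomy

The organising structure is a four-level acyclic tree: **themes** (level 1)
group data by common usage or modality; **domains** (level 2) and
**families** (level 3) narrow the construct; **objects** (level 4) are
individual measured variables. Level granularity follows how variables are
actually requested from data-access committees — a request is typically for
"all processing speed variables" rather than a single reaction-time task, so
constructs of that width sit at domain level. The grouping is pragmatic, not
nosological: a theme may be user-defined (Cognitive status) or
technology-defined (Imaging), and disease-code usage inside labels is a
labelling choice, not a coding engine.

Structural invariants enforced at load time:

* exactly four levels; every leaf is a level-4 object and every object is a
  leaf;
* child level = parent level + 1 (no skipping);
* sibling labels unique, compared case-insensitively and
  whitespace-normalised (source typography is inconsistent, so matching must
  not be literal);
* theme indices unique integers — they are *printed* numbers, not ordinals,
  hence non-contiguous in the harmonised subset (2, 4, 5, 6, 7, 8, 12, 13,
  16, 17).

Two shipped documents: `table1_taxonomy.yaml`, the fully specified
32-object harmonised subset; and `reference_taxonomy.yaml`, all 18 theme
slots. Eight of the reference themes are stubs flagged `provisional: true`
(their labels or content are not settled); provisional nodes are the one
sanctioned exception to the leaf rule, so the theme count is honest without
inventing content. Two flattening decisions were needed to make the
harmonised subset machine-readable: "Episodic disorders" and "Other
neurological disorders" are modelled as single-object families (the object
is the disorder group itself), and the family-history families record the
family-member relation in the family column rather than as an extra level —
the only reading consistent with a 32-object total. The reference document
additionally carries Height and Weight objects under Physical examination /
Musculo-skeletal / Structural: these are the anthropometry variables the
metric-conversion conventions are defined for, and the synthetic default
battery needs resolvable paths for them; the harmonised subset itself is
left untouched.

### Naming grammar

`COHORT_MEASUREMENT[q<item>]_<serial>_<wave>`. The underscore is reserved as
the element separator (both worked examples use it only as such), which
makes parsing unambiguous: a name has exactly four underscore-separated
elements.

Parameters and limits:

* cohort code: exactly 3 alphabetic characters, canonical upper-case;
* measurement abbreviation: ≤ 12 characters for survey data, ≤ 17 for
  imaging/omics/device data. The `q<digits>` item suffix never counts toward
  the budget (it is grammar, not abbreviation — this keeps item-level names
  of long instruments legal); a `DX` suffix does count, so marking a
  12-character survey measure as diagnosed is a length error. Both choices
  are exposed as `count_q_suffix` / `count_dx_suffix` arguments for
  deployments that read the budget differently.
* serial ≥ 0, with 0 meaning "not repeated within the capture period";
  serial 0 and serial 1 are distinct states, not synonyms. Wave is 1-based
  (1 = recruitment).
* lower-case characters are reserved for the constant markers `q`
  (question), `r` (range), `d` (decimal point).

Case handling: parsing is case-insensitive; canonical output upper-cases
everything except marker positions. Markers are inferred from lower-case
q/r/d only in *mixed-case* input — single-cased input carries no case
information and is upper-cased wholesale (`painchestevr` →
`PAINCHESTEVR`, even though it contains an `r`). Equality between names is
therefore case-insensitive by construction. A measurement may not *end* in
`q` followed by digits unless an item is meant: that surface form is the
item suffix, and permitting it would break the parse/format round trip (the
round-trip property test is what surfaces this).

DX detection is a heuristic: the grammar alone cannot distinguish a
diagnosed `PTSDDX` from a measurement that innocently ends in the letters
DX, so the latter must be declared `diagnosed_exempt` in its mapping.

### Value conventions

* **Missing** means absence of recorded data, as indicated by the cohort.
  Internally it is the pandas NA sentinel; the Stata-style literal `.`
  exists only at the CSV boundary (an in-memory `"."` would collide with
  decimal strings). Curated CSVs are read with *only* `.` as missing —
  native markers like `NA` or blank are data at that layer.
* **Informative non-response** ("don't know", "prefer not to answer") is
  retained as a value, never converted to missing, so that exclusion
  decisions stay with the analyst. Non-response codes keep their native
  values by default; an opt-in `nonresponse_remap` rule moves them to a
  reserved range for cohorts that want one.
* **Gender**: 2 = female, 1 = male, identified from native *labels*
  (case-insensitive match on female/f/woman and male/m/man). Positional
  guessing is forbidden: unrecognisable labels are an error demanding an
  explicit `custom_map`. Unmatched categories (e.g. intersex) pass through
  unchanged and are audited, never dropped.
* **Units**: conversion factors are exact legal definitions (international
  inch 2.54 cm, pound 0.45359237 kg, stone 6.35029318 kg, foot 30.48 cm).
  Values are stored at full float precision — rounding is a display
  concern. Round trips are accurate to well below 1e−9 relative error
  (measured, not assumed: the acceptance script reports the worst observed
  error).

Every recode result carries the untouched native label map next to the
curated one, and an audit of affected cell counts per rule.

### Curation

A mapping spec is validated before any data is touched: grammar conformance
of every target name, uniqueness of targets, cohort-code consistency,
taxonomy paths resolving to level-4 objects, and presence of every native
column (misses are collected and reported together, not one at a time).
Curated output is wide — one row per participant — because wave and serial
are embedded in the column name. Unmapped native columns are excluded (the
curated artifact must be fully conformant) but listed in the report, so
nothing disappears silently. The participant identifier column is named
`id` and excluded from grammar checks; no identifier convention exists
upstream, so this is a package choice. Outputs are deterministic:
identical inputs give byte-identical `curated.csv`, `dictionary.csv`,
`dictionary.json` and `report.json`.

### Feasibility engine

Filters are conjunctive only, matching how a feasibility dashboard is
used; disjunction is out of scope. A missing value fails every predicate
except an explicit `missing` one — funnels measure *usable complete data*,
which is the quantity that matters when planning a data-access request.
Informative non-response counts as data present in availability (it is
information); this default is a judgement call and is easy to tighten with
an additional `in`-predicate step for callers who consider "don't know"
unusable. Counts of distinct participants come free with the wide layout.
Only counts leave the API surface, mirroring the access-controlled setting
the engine models.

z-scoring uses the sample standard deviation (ddof = 1) by default with a
population option; columns with fewer than two non-missing values or zero
spread raise a degenerate-scale error rather than emitting NaNs.

## The synthetic-data generator

`default_blueprints()` defines the default study conditions: a ten-variable
survey battery for an ageing cohort — year of birth, age (mean 62, sd 9),
sex, years of education, smoking status, weekly alcohol units, height
(inches, mean 66, sd 4), weight (pounds, mean 165, sd 30), a 0–27
depression scale, and reaction time (ms, mean 450, sd 80). Missingness
rises from administrative items (1–3%) through survey items (5–10%) to
burdensome tasks (15%), and self-report items carry labelled non-response
at 1–3% — rates chosen once as typical of such studies. Naming styles are
mixed (snake_case, CamelCase, cryptic positional codes) and the native
missing code varies by style (−9, −99, blank) to exercise the recoder's
breadth. `table1_blueprints()` instead emits one generic variable per
object of the 32-object harmonised subset, for dictionary-wide
demonstrations.

The generator draws curated-equivalent values and derives the native cell
(imperial value × exact factor, label-mapped gender code), recording the
expected curated value at the same moment; the truth manifest therefore
gives *exact* cell-level oracles, not distributional ones. Draws use
numpy's PCG64; uniform-integer paths drive all categorical and indicator
draws, and identical config + seed reproduces byte-identical CSV output. A
drawn value colliding with a declared missing/non-response code is an
error at generation time, so truth comparisons can demand exact equality.

`plant_funnel` generates cohorts whose filter indicators are independent
Bernoulli draws at stated pass rates, and computes expected funnel counts
by tallying the drawn conjunctions — again exact, so the engine must match
to the participant.

What the generator does **not** emulate: correlated missingness
(missing-not-at-random), inter-variable correlation structure,
heavy-tailed or skewed continuous distributions (Gaussian only in this
version), measurement error, long/multi-row native layouts, or free-text
fields. Tests passing on these cohorts show the *pipeline mechanics* —
naming, recoding, dictionary generation, counting — are exact; they say
nothing about the semantic quality of any real cohort's mapping spec,
which remains expert work (automated mapping suggestion is explicitly out
of scope).

## Problem sizes

The test suite and acceptance script run synthetic cohorts of 200–2,000
participants and funnels over 3 cohorts × 1,000 participants. These sizes
were chosen because every oracle here is exact (cell-level equality,
indicator tallies): once the mechanics match at n = 1,000, larger n probes
nothing new, and the whole suite stays fast enough to run on every change.

## Known limitations

* The taxonomy ships the harmonised reference subset plus theme stubs, not
  the full several-hundred-node hierarchy, which is not published in full;
  the loader and validator are size-agnostic.
* Ingestion expects pre-derived variables in delimited tables. Raw imaging,
  omics, EHR or accelerometry data must be pre-processed to derived
  variables before curation; proprietary binary formats are not read.
* The DX heuristic and the gender label matcher are deliberately
  conservative; both fail loudly rather than guess.
* Harmonisation here means declared per-cohort bindings plus simple scale
  standardisation; construct-equivalence judgements (are two depression
  scales the same latent construct?) are inputs, not outputs.
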