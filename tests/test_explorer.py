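"""Feasibility engine: availability, funnels, standardisation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from csurv.curate import CuratedDataset, apply_mapping
from csurv.errors import DegenerateScaleError, FilterConfigError, IntegrityError
from csurv.explorer import (
    FilterStep,
    HarmonisedVariable,
    availability,
    funnel,
    standardise,
)
from csurv.recode import is_missing
from csurv.synthcohort import (
    SynthConfig,
    default_blueprints,
    generate_native_cohort,
    plant_funnel,
)


@pytest.fixture(scope="module")
def three_cohorts(ref_tax):
    """Three seeded cohorts curated from the default battery."""
    cohorts = []
    for code, seed in (("AAA", 1), ("BBB", 2), ("CCC", 3)):
        config = SynthConfig(
            cohort_code=code, n_participants=300, variables=default_blueprints(), seed=seed
        )
        native, manifest = generate_native_cohort(config)
        cohorts.append(apply_mapping(native, manifest.spec, ref_tax))
    return cohorts


def _var(label, measurement, cohorts):
    return HarmonisedVariable(
        label=label,
        per_cohort_object={c.cohort_code: f"{c.cohort_code}_{measurement}_0_1" for c in cohorts},
    )


class TestAvailability:
    def test_matches_brute_force_tallies(self, three_cohorts):
        variables = [
            _var("Age", "AGE", three_cohorts),
            _var("Smoking status", "SMOKSTAT", three_cohorts),
            _var("Reaction time", "REACTIME", three_cohorts),
        ]
        matrix = availability(three_cohorts, variables)
        for var in variables:
            for ds in three_cohorts:
                col = var.per_cohort_object[ds.cohort_code]
                brute = sum(1 for v in ds.table[col] if not is_missing(v))
                assert matrix.counts.loc[var.label, ds.cohort_code] == brute

    def test_nonresponse_counts_as_data_present(self, three_cohorts):
        ds = three_cohorts[0]
        col = f"{ds.cohort_code}_SMOKSTAT_0_1"
        n_dontknow = sum(1 for v in ds.table[col] if not is_missing(v) and int(v) == 8)
        assert n_dontknow > 0  # the battery plants "don't know" answers
        matrix = availability([ds], [_var("Smoking status", "SMOKSTAT", [ds])])
        count = matrix.counts.loc["Smoking status", ds.cohort_code]
        complete = sum(1 for v in ds.table[col] if not is_missing(v) and int(v) != 8)
        assert count == complete + n_dontknow

    def test_absent_variable_yields_zero_and_flag(self, three_cohorts):
        var = HarmonisedVariable(
            label="CSF Tau", per_cohort_object={"AAA": "AAA_CSFTAU_0_1"}
        )
        matrix = availability(three_cohorts, [var])
        assert matrix.counts.loc["CSF Tau", "BBB"] == 0
        assert ("CSF Tau", "BBB") in matrix.absent
        assert ("CSF Tau", "AAA") in matrix.absent  # bound but not curated here

    def test_empty_cohort_all_zero(self, ref_tax):
        config = SynthConfig(cohort_code="EEE", n_participants=0,
                             variables=default_blueprints(), seed=9)
        native, manifest = generate_native_cohort(config)
        ds = apply_mapping(native, manifest.spec, ref_tax)
        matrix = availability([ds], [_var("Age", "AGE", [ds])])
        assert (matrix.counts.to_numpy() == 0).all()

    def test_duplicate_ids_are_an_integrity_error(self):
        table = pd.DataFrame({"id": ["a", "a"], "XXX_AGE_0_1": [1, 2]})
        ds = CuratedDataset(cohort_code="XXX", table=table, dictionary=[], report={})
        with pytest.raises(IntegrityError):
            availability([ds], [])


class TestFunnel:
    def test_planted_counts_match_exactly(self):
        pf = plant_funnel(["AAA", "BBB", "CCC"], 1000, [0.5, 0.4, 0.9], seed=11)
        res = funnel(pf.cohorts, pf.steps)
        assert res.base == pf.expected.base
        for got, exp in zip(res.steps, pf.expected.steps):
            assert got.per_cohort == exp.per_cohort
            assert got.pooled == exp.pooled

    def test_brute_force_sequential_filtering(self, three_cohorts):
        steps = [
            FilterStep(_var("Age", "AGE", three_cohorts), "ge", 50),
            FilterStep(_var("Smoking status", "SMOKSTAT", three_cohorts), "eq", 0),
            FilterStep(_var("Depression scale", "DEPSCALE", three_cohorts), "le", 9),
        ]
        res = funnel(three_cohorts, steps)
        for ds in three_cohorts:
            code = ds.cohort_code
            keep = np.ones(len(ds.table), dtype=bool)
            checks = [
                (f"{code}_AGE_0_1", lambda v: float(v) >= 50),
                (f"{code}_SMOKSTAT_0_1", lambda v: float(v) == 0),
                (f"{code}_DEPSCALE_0_1", lambda v: float(v) <= 9),
            ]
            for k, (col, pred) in enumerate(checks):
                ok = ds.table[col].map(lambda v: (not is_missing(v)) and pred(v))
                keep &= ok.to_numpy(dtype=bool)
                assert res.steps[k].per_cohort[code] == int(keep.sum())

    def test_single_nonmissing_step_equals_availability(self, three_cohorts):
        var = _var("Height", "HEIGHT", three_cohorts)
        res = funnel(three_cohorts, [FilterStep(var, "nonmissing")])
        matrix = availability(three_cohorts, [var])
        for ds in three_cohorts:
            assert res.steps[0].per_cohort[ds.cohort_code] == \
                matrix.counts.loc["Height", ds.cohort_code]

    def test_repeated_step_is_idempotent(self, three_cohorts):
        step = FilterStep(_var("Age", "AGE", three_cohorts), "ge", 60)
        res = funnel(three_cohorts, [step, step])
        assert res.steps[0].per_cohort == res.steps[1].per_cohort

    def test_final_count_invariant_under_step_permutation(self, three_cohorts):
        steps = [
            FilterStep(_var("Age", "AGE", three_cohorts), "ge", 55),
            FilterStep(_var("Smoking status", "SMOKSTAT", three_cohorts), "in",
                       values=frozenset({0, 1})),
            FilterStep(_var("Sex", "SEX", three_cohorts), "eq", 2),
        ]
        finals = set()
        for perm in itertools.permutations(steps):
            res = funnel(three_cohorts, list(perm))
            finals.add(tuple(sorted(res.steps[-1].per_cohort.items())))
        assert len(finals) == 1

    def test_pooled_is_sum_of_cohorts(self, three_cohorts):
        steps = [FilterStep(_var("Age", "AGE", three_cohorts), "ge", 50)]
        res = funnel(three_cohorts, steps)
        assert res.base_pooled == sum(res.base.values())
        for s in res.steps:
            assert s.pooled == sum(s.per_cohort.values())

    def test_missing_fails_every_predicate_except_missing(self):
        table = pd.DataFrame({"id": ["a", "b"], "XXX_V_0_1": [pd.NA, 5]})
        ds = CuratedDataset(cohort_code="XXX", table=table, dictionary=[], report={})
        var = HarmonisedVariable(label="v", per_cohort_object={"XXX": "XXX_V_0_1"})
        assert funnel([ds], [FilterStep(var, "ge", 0)]).steps[0].pooled == 1
        assert funnel([ds], [FilterStep(var, "missing")]).steps[0].pooled == 1

    def test_type_incompatible_predicate_names_the_step(self, three_cohorts):
        step = FilterStep(_var("Smoking status", "SMOKSTAT", three_cohorts), "ge", "never")
        with pytest.raises(FilterConfigError, match="Smoking"):
            funnel(three_cohorts, [step])

    def test_empty_step_list_rejected(self, three_cohorts):
        with pytest.raises(FilterConfigError):
            funnel(three_cohorts, [])

    @given(
        ops=st.lists(
            st.tuples(st.sampled_from(["ge", "le", "eq", "nonmissing"]),
                      st.integers(-5, 60)),
            min_size=1, max_size=5,
        )
    )
    def test_monotonicity_for_random_predicate_sequences(self, ops):
        pf = plant_funnel(["MMM"], 120, [0.7], seed=13)
        ds = pf.cohorts[0]
        var = HarmonisedVariable(label="age-ish", per_cohort_object={"MMM": "MMM_FLT1_0_1"})
        steps = [FilterStep(var, op, value if op != "nonmissing" else None)
                 for op, value in ops]
        res = funnel([ds], steps)
        counts = [res.base_pooled] + [s.pooled for s in res.steps]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestStandardise:
    def test_zscore_symmetric_triplet(self):
        z = standardise([1, 2, 3])
        vals = [float(v) for v in z]
        assert vals[1] == pytest.approx(0.0)
        assert float(np.mean(vals)) == pytest.approx(0.0)
        assert float(np.std(vals, ddof=1)) == pytest.approx(1.0)

    def test_constant_column_is_degenerate(self):
        with pytest.raises(DegenerateScaleError):
            standardise([5, 5, 5])

    def test_planted_moments_recovered(self):
        rng = np.random.default_rng(99)
        x = rng.normal(10, 2, 1000)
        z = standardise(list(x))
        vals = np.array([float(v) for v in z])
        assert abs(vals.mean()) <= 0.1
        assert abs(vals.std(ddof=1) - 1) <= 0.05

    def test_missing_preserved(self):
        z = standardise([1, pd.NA, 3])
        assert is_missing(z[1]) and not is_missing(z[0])

    def test_population_denominator_option(self):
        z = standardise([1, 2, 3], ddof=0)
        vals = np.array([float(v) for v in z])
        assert np.std(vals, ddof=0) == pytest.approx(1.0)

    def test_rescale_to_unit_interval(self):
        z = standardise([2, 4, 6], transform="rescale")
        assert [float(v) for v in z] == [0.0, 0.5, 1.0]
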