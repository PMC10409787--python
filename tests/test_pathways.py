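"""Pathway completeness calls, role labeling, and the size comparison."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vitnet.io import AnnotationSet, PathwayCatalog
from vitnet.pathways import (
    STATUS_ORDER,
    CapabilityCall,
    call_pathway,
    classify_roles,
    vitamin_count_vs_size,
)


def complete_thiamine_kos(catalog):
    return frozenset(next(iter(s.kos)) for s in catalog.vitamins["thiamine"])


def oracle_status(genome_kos, stages, exempt):
    """Brute-force oracle: literal evaluation of the tier definitions."""
    unsat = [s for s in stages if not (s["kos"] & genome_kos)]
    if not unsat:
        return "complete"
    if all(s["kos"] <= exempt for s in unsat):
        return "near_complete"
    return "absent"


class TestCallPathway:
    def test_one_ko_per_stage_is_complete(self, catalog):
        ann = AnnotationSet({"gA": complete_thiamine_kos(catalog)})
        call = call_pathway(ann, catalog, "gA", "thiamine")
        assert call.status == "complete"
        assert call.satisfied_stages == frozenset(catalog.stage_names("thiamine"))
        assert call.missing_kos == frozenset()

    def test_lacking_only_thic_is_near_complete(self, catalog):
        kos = complete_thiamine_kos(catalog) | {"K03149"}
        ann = AnnotationSet({"gA": kos - {"K03147"}})
        call = call_pathway(ann, catalog, "gA", "thiamine")
        assert call.status == "near_complete"
        assert call.missing_kos == frozenset({"K03147"})

    def test_missing_thiazole_stage_is_absent(self, catalog):
        thiazole = catalog.vitamins["thiamine"][0]
        assert thiazole.name == "thiazole_production"
        kos = complete_thiamine_kos(catalog) - thiazole.kos
        ann = AnnotationSet({"gA": kos})
        assert call_pathway(ann, catalog, "gA", "thiamine").status == "absent"

    def test_unknown_vitamin_or_genome_rejected(self, catalog):
        ann = AnnotationSet({"gA": frozenset()})
        with pytest.raises(KeyError):
            call_pathway(ann, catalog, "gA", "cobalamin")
        with pytest.raises(KeyError):
            call_pathway(ann, catalog, "gZ", "thiamine")

    def test_empty_ko_set_is_absent(self, catalog):
        ann = AnnotationSet({"gA": frozenset()})
        assert call_pathway(ann, catalog, "gA", "thiamine").status == "absent"

    def test_oracle_equivalence_on_random_catalogs(self):
        rng = np.random.default_rng(12)
        universe = [f"K{i:05d}" for i in range(40)]
        for trial in range(200):
            n_stages = int(rng.integers(1, 5))
            stages = []
            used = set()
            for s in range(n_stages):
                size = int(rng.integers(1, 4))
                kos = set(rng.choice(universe, size=size, replace=False))
                stages.append({"name": f"st{s}", "kos": frozenset(kos)})
                used |= kos
            exempt = set()
            if used and rng.random() < 0.6:
                exempt = set(
                    rng.choice(sorted(used), size=int(rng.integers(1, 3)))
                )
            cat = PathwayCatalog.from_dict(
                {
                    "v": {
                        "stages": [
                            {"name": s["name"], "kos": sorted(s["kos"])}
                            for s in stages
                        ],
                        "near_complete_exempt_kos": sorted(exempt),
                    }
                }
            )
            genome = frozenset(
                ko for ko in universe if rng.random() < 0.35
            )
            ann = AnnotationSet({"g": genome})
            got = call_pathway(ann, cat, "g", "v").status
            want = oracle_status(genome, stages, frozenset(exempt))
            assert got == want, (trial, genome, stages, exempt)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    genome=st.sets(st.sampled_from([f"K{i:05d}" for i in range(12)])),
    extra=st.sampled_from([f"K{i:05d}" for i in range(12)]),
)
def test_adding_a_ko_never_demotes_status(genome, extra):
    """Monotonicity: absent -> near_complete -> complete only moves right."""
    cat = PathwayCatalog.from_dict(
        {
            "v": {
                "stages": [
                    {"name": "s1", "kos": ["K00000", "K00001"]},
                    {"name": "s2", "kos": ["K00002"]},
                    {"name": "s3", "kos": ["K00003", "K00004"]},
                ],
                "near_complete_exempt_kos": ["K00002"],
            }
        }
    )
    before = call_pathway(AnnotationSet({"g": frozenset(genome)}), cat, "g", "v")
    after = call_pathway(
        AnnotationSet({"g": frozenset(genome) | {extra}}), cat, "g", "v"
    )
    assert STATUS_ORDER[after.status] >= STATUS_ORDER[before.status]


class TestClassifyRoles:
    def _call(self, g, status):
        return CapabilityCall(g, "thiamine", status, frozenset(), frozenset())

    def test_basic_partition(self):
        calls = [
            self._call("a", "complete"),
            self._call("b", "absent"),
            self._call("c", "absent"),
        ]
        labels = classify_roles(calls, "thiamine")
        assert labels.n_producers == 1 and labels.n_auxotrophs == 2
        assert labels.n_producers + labels.n_auxotrophs == 3

    @pytest.mark.parametrize(
        "policy,expected", [("producer", "producer"), ("auxotroph", "auxotroph")]
    )
    def test_near_complete_policy(self, policy, expected):
        labels = classify_roles(
            [self._call("a", "near_complete")], "thiamine", policy
        )
        assert labels.roles["a"] == expected

    def test_empty_calls(self):
        labels = classify_roles([], "thiamine")
        assert labels.n_producers == 0 and labels.n_auxotrophs == 0

    def test_duplicate_genome_rejected(self):
        calls = [self._call("a", "complete"), self._call("a", "absent")]
        with pytest.raises(ValueError, match="duplicate"):
            classify_roles(calls, "thiamine")


class TestVitaminCountVsSize:
    def _ann_and_calls(self, lengths, counts):
        vitamins = ["thiamine", "biotin", "tetrahydrofolate", "riboflavin",
                    "NAD", "pantothenate"]
        calls = []
        for g, c in counts.items():
            for i, vit in enumerate(vitamins):
                status = "complete" if i < c else "absent"
                calls.append(CapabilityCall(g, vit, status, frozenset(), frozenset()))
        return AnnotationSet({g: frozenset() for g in counts}, lengths), calls

    def test_counting_and_binning(self):
        ann, calls = self._ann_and_calls(
            {"a": 100, "b": 200}, {"a": 3, "b": 5}
        )
        res = vitamin_count_vs_size(ann, calls)
        assert res.counts == {"a": 3, "b": 5}
        assert res.bins["3"]["n"] == 1 and res.bins["5-6"]["n"] == 1

    def test_welch_matches_hand_computation(self):
        ann, calls = self._ann_and_calls(
            {f"g{i}": l for i, l in enumerate([10, 12, 11, 20, 22, 21])},
            {"g0": 2, "g1": 2, "g2": 2, "g3": 3, "g4": 3, "g5": 3},
        )
        res = vitamin_count_vs_size(ann, calls)
        # hand Welch: means 11, 21; s^2 = 1 each, n = 3
        t_hand = (11 - 21) / math.sqrt(1 / 3 + 1 / 3)
        assert res.tests[("2", "3")]["t"] == pytest.approx(t_hand)
        # Welch-Satterthwaite df = 4 here
        from scipy import stats

        p_hand = 2 * stats.t.sf(abs(t_hand), df=4)
        assert res.tests[("2", "3")]["p"] == pytest.approx(p_hand)

    def test_identical_distributions_give_null_result(self):
        ann, calls = self._ann_and_calls(
            {"a": 10, "b": 12, "c": 11, "d": 10, "e": 12, "f": 11},
            {"a": 2, "b": 2, "c": 2, "d": 3, "e": 3, "f": 3},
        )
        res = vitamin_count_vs_size(ann, calls)
        assert res.tests[("2", "3")]["t"] == pytest.approx(0.0)
        assert res.tests[("2", "3")]["p"] == pytest.approx(1.0)

    def test_underfilled_bin_not_computable(self):
        ann, calls = self._ann_and_calls({"a": 10, "b": 11}, {"a": 2, "b": 2})
        res = vitamin_count_vs_size(ann, calls)
        assert res.tests[("2", "3")] is None

    def test_genome_without_length_excluded(self):
        ann, calls = self._ann_and_calls({"a": 10}, {"a": 2, "b": 2})
        res = vitamin_count_vs_size(ann, calls)
        assert res.bins["2"]["n"] == 1
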