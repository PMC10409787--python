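"""Per-genome vitamin-pathway completeness calls and producer/auxotroph roles.

A pathway is an ordered list of stages, each satisfiable by any one of a set
of alternative KEGG orthologs (KOs). A genome is *complete* for a vitamin
when every stage is satisfied, *near_complete* when every unsatisfied stage
could only have been satisfied by KOs in the catalog's exempt set (for
thiamine: thiC / K03147, phosphomethylpyrimidine synthase), and *absent*
otherwise. Producers are complete genomes, plus near-complete genomes under
the default policy; every non-producer is treated as an auxotroph for the
network analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from vitnet.io import AnnotationSet, PathwayCatalog

STATUS_ORDER = {"absent": 0, "near_complete": 1, "complete": 2}

#: genome-size bins of the vitamin-breadth comparison (counts of complete
#: pathways out of the six shipped vitamins)
DEFAULT_BINS: tuple[tuple[str, tuple[int, ...]], ...] = (
    ("0-1", (0, 1)),
    ("2", (2,)),
    ("3", (3,)),
    ("4", (4,)),
    ("5-6", (5, 6)),
)


@dataclass(frozen=True)
class CapabilityCall:
    genome_id: str
    vitamin: str
    status: str  # complete | near_complete | absent
    satisfied_stages: frozenset[str]
    missing_kos: frozenset[str]


@dataclass
class RoleLabels:
    """Producer/auxotroph dichotomy over a node set for one vitamin."""

    vitamin: str
    roles: dict[str, str]  # node -> "producer" | "auxotroph"
    near_complete_policy: str = "producer"

    def __post_init__(self) -> None:
        bad = {r for r in self.roles.values()} - {"producer", "auxotroph"}
        if bad:
            raise ValueError(f"unknown role(s): {sorted(bad)}")

    @property
    def producers(self) -> list[str]:
        return [v for v, r in self.roles.items() if r == "producer"]

    @property
    def auxotrophs(self) -> list[str]:
        return [v for v, r in self.roles.items() if r == "auxotroph"]

    @property
    def n_producers(self) -> int:
        return len(self.producers)

    @property
    def n_auxotrophs(self) -> int:
        return len(self.auxotrophs)

    def restricted_to(self, nodes: Iterable[str]) -> "RoleLabels":
        nodes = set(nodes)
        missing = nodes - set(self.roles)
        if missing:
            raise KeyError(f"nodes without role labels: {sorted(missing)[:5]}")
        return RoleLabels(
            self.vitamin,
            {v: r for v, r in self.roles.items() if v in nodes},
            self.near_complete_policy,
        )


def call_pathway(
    ann: AnnotationSet, cat: PathwayCatalog, genome_id: str, vitamin: str
) -> CapabilityCall:
    """Call one genome's completeness status for one vitamin.

    A stage is satisfied iff its alternative-KO set intersects the genome's
    KO set. ``missing_kos`` collects the absent KOs of unsatisfied stages.
    """
    if vitamin not in cat.vitamins:
        raise KeyError(f"vitamin {vitamin!r} not in catalog")
    if genome_id not in ann.kos:
        raise KeyError(f"genome {genome_id!r} not in annotation set")
    genome_kos = ann.kos[genome_id]
    exempt = cat.near_complete_exempt_kos.get(vitamin, frozenset())
    satisfied: set[str] = set()
    missing: set[str] = set()
    unsat_within_exempt = True
    for stage in cat.vitamins[vitamin]:
        if stage.kos & genome_kos:
            satisfied.add(stage.name)
        else:
            missing |= stage.kos - genome_kos
            if not stage.kos <= exempt:
                unsat_within_exempt = False
    if len(satisfied) == len(cat.vitamins[vitamin]):
        status = "complete"
    elif unsat_within_exempt:
        status = "near_complete"
    else:
        status = "absent"
    return CapabilityCall(
        genome_id, vitamin, status, frozenset(satisfied), frozenset(missing)
    )


def call_all_pathways(
    ann: AnnotationSet, cat: PathwayCatalog, genome_ids: Sequence[str] | None = None
) -> list[CapabilityCall]:
    genomes = list(genome_ids) if genome_ids is not None else ann.genome_ids
    return [
        call_pathway(ann, cat, g, vit)
        for g in genomes
        for vit in cat.vitamin_names
    ]


def classify_roles(
    calls: Sequence[CapabilityCall],
    vitamin: str,
    near_complete_policy: str = "producer",
) -> RoleLabels:
    """Derive producer/auxotroph labels from capability calls for a vitamin.

    Producers are complete genomes; near-complete genomes count as producers
    under ``policy="producer"`` (the default, matching the treatment of
    near-complete thiamine pathways as capable) and as auxotrophs otherwise.
    """
    if near_complete_policy not in ("producer", "auxotroph"):
        raise ValueError(f"unknown policy {near_complete_policy!r}")
    roles: dict[str, str] = {}
    for call in calls:
        if call.vitamin != vitamin:
            continue
        if call.genome_id in roles:
            raise ValueError(f"duplicate call for genome {call.genome_id!r}")
        producer = call.status == "complete" or (
            call.status == "near_complete" and near_complete_policy == "producer"
        )
        roles[call.genome_id] = "producer" if producer else "auxotroph"
    return RoleLabels(vitamin, roles, near_complete_policy)


@dataclass
class SizeComparison:
    """Genome length compared across vitamin-breadth bins."""

    bins: dict[str, dict]  # label -> {n, mean_length_bp, lengths}
    tests: dict[tuple[str, str], dict | None]  # pair -> {t, p} or None
    counts: dict[str, int]  # genome -> number of complete vitamin pathways


def vitamin_count_vs_size(
    ann: AnnotationSet,
    calls: Sequence[CapabilityCall],
    bins: Sequence[tuple[str, Sequence[int]]] = DEFAULT_BINS,
    count_near_complete: bool = False,
) -> SizeComparison:
    """Relate the number of encoded vitamin pathways to genome size.

    Each genome's vitamin count is its number of complete pathways (optionally
    including near-complete ones); genomes are binned by count and genome
    lengths compared pairwise between bins with Welch's two-sided t-test
    (unequal variances). Bins with fewer than 2 genomes yield no test.
    Genomes without a recorded length are excluded.
    """
    counts: dict[str, int] = {}
    for call in calls:
        counts.setdefault(call.genome_id, 0)
        ok = call.status == "complete" or (
            count_near_complete and call.status == "near_complete"
        )
        if ok:
            counts[call.genome_id] += 1
    bin_lengths: dict[str, list[int]] = {label: [] for label, _ in bins}
    membership = {c: label for label, cs in bins for c in cs}
    for genome, count in counts.items():
        if genome not in ann.lengths:
            continue
        label = membership.get(count)
        if label is not None:
            bin_lengths[label].append(ann.lengths[genome])
    bins_out = {
        label: {
            "n": len(lengths),
            "mean_length_bp": float(np.mean(lengths)) if lengths else None,
            "lengths": lengths,
        }
        for label, lengths in bin_lengths.items()
    }
    tests: dict[tuple[str, str], dict | None] = {}
    for (la, _), (lb, _) in combinations(bins, 2):
        a, b = bin_lengths[la], bin_lengths[lb]
        if len(a) < 2 or len(b) < 2:
            tests[(la, lb)] = None
            continue
        t, p = stats.ttest_ind(a, b, equal_var=False)
        tests[(la, lb)] = {"t": float(t), "p": float(p)}
    return SizeComparison(bins_out, tests, counts)
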