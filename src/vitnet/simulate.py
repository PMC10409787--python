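"""Synthetic bioreactor-style communities with planted structure.

The generator emulates a time-series metagenome collection: ~120 genomes
observed across 92 samples as compositional relative abundances, with

* positively-correlated genome modules planted on the latent (basis) log
  scale (within-module correlation ``rho_in``),
* a planted vitamin-producer hub whose dependent neighbors are auxotrophs
  correlated with it at ``rho_hub`` (the dependents load on the hub's latent
  factor, so their pairwise correlation is ``rho_hub**2``),
* multinomial count noise at a fixed sequencing depth followed by closure to
  relative abundance — the compositional distortion the SparCC estimator is
  meant to see through,
* KO annotation sets consistent with each genome's planted producer /
  near-complete / auxotroph role under the shipped pathway catalog, and
* genome lengths that grow with the number of planted pathways.

Everything is a deterministic function of the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from vitnet.io import (
    AbundanceTable,
    AnnotationSet,
    PathwayCatalog,
    SampleMetadata,
)

#: producer fraction defaults; thiamine mirrors a 38-of-120 producer split
DEFAULT_PRODUCER_FRACTIONS = {
    "thiamine": 38 / 120,
    "biotin": 0.45,
    "tetrahydrofolate": 0.55,
    "riboflavin": 0.60,
    "NAD": 0.70,
    "pantothenate": 0.35,
}


@dataclass
class SyntheticSpec:
    """Parameters of the planted community; defaults emulate the study scale
    (120 genomes x 92 samples, four correlated modules, one producer hub with
    eight dependent auxotrophs, 38 thiamine producers)."""

    n_genomes: int = 120
    n_samples: int = 92
    module_sizes: tuple[int, ...] = (25, 25, 25, 25)
    rho_in: float = 0.7
    rho_out: float = 0.0
    hub_id: str = "g001"
    n_dependents: int = 8
    rho_hub: float = 0.8
    producer_fractions: dict = field(
        default_factory=lambda: dict(DEFAULT_PRODUCER_FRACTIONS)
    )
    near_complete_fraction: float = 0.1
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.0
    depth: int = 100_000
    # per-module log-abundance shift in (planktonic, high-SCN) samples
    lifestyle_shift: dict = field(default_factory=lambda: {1: 1.0})
    scn_shift: dict = field(default_factory=lambda: {2: 1.0})
    n_decoy_kos: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.module_sizes) + 1 + self.n_dependents > self.n_genomes:
            raise ValueError("module sizes plus hub group exceed n_genomes")
        for name, rho in (("rho_in", self.rho_in), ("rho_out", self.rho_out),
                          ("rho_hub", self.rho_hub)):
            if not (0.0 <= rho < 1.0):
                raise ValueError(f"{name} must lie in [0, 1)")
        for vit, frac in self.producer_fractions.items():
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"producer fraction for {vit!r} outside [0, 1]")
        if self.depth < 1:
            raise ValueError("depth must be positive")


@dataclass
class SyntheticTruth:
    basis_correlation: np.ndarray
    genome_ids: list[str]
    module_of: dict[str, int]  # -1 = background, 0 = hub group
    roles: dict[str, dict[str, str]]  # vitamin -> genome -> role
    statuses: dict[str, dict[str, str]]  # vitamin -> genome -> status
    hub_id: str
    dependents: list[str]
    lengths: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "genome_ids": self.genome_ids,
            "module_of": self.module_of,
            "roles": self.roles,
            "statuses": self.statuses,
            "hub_id": self.hub_id,
            "dependents": self.dependents,
            "lengths": self.lengths,
        }


def _build_correlation(spec: SyntheticSpec, ids: list[str]) -> tuple[np.ndarray, dict]:
    """Latent log-scale correlation matrix with planted blocks."""
    n = spec.n_genomes
    sigma = np.full((n, n), spec.rho_out)
    np.fill_diagonal(sigma, 1.0)
    module_of = {g: -1 for g in ids}

    # hub group: hub + dependents load on one factor
    hub_idx = 0
    dep_idx = list(range(1, 1 + spec.n_dependents))
    group = [hub_idx] + dep_idx
    for g in group:
        module_of[ids[g]] = 0
    for a in dep_idx:
        sigma[hub_idx, a] = sigma[a, hub_idx] = spec.rho_hub
        for b in dep_idx:
            if a != b:
                sigma[a, b] = sigma[b, a] = spec.rho_hub**2

    start = 1 + spec.n_dependents
    for mod, size in enumerate(spec.module_sizes, start=1):
        members = list(range(start, start + size))
        for g in members:
            module_of[ids[g]] = mod
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                sigma[a, b] = sigma[b, a] = spec.rho_in
        start += size

    eig = np.linalg.eigvalsh(sigma)
    if eig.min() < -1e-8:
        raise ValueError(
            "planted correlation structure is not positive semidefinite "
            f"(min eigenvalue {eig.min():.3g}); check rho_in/rho_hub blocks"
        )
    return sigma, module_of


def _stratified_producers(
    spec: SyntheticSpec,
    ids: list[str],
    module_of: dict[str, int],
    n_prod: int,
    rng: np.random.Generator,
) -> list[str]:
    """Thiamine producers: the hub, plus producers spread across modules.

    Producer capability is widespread, so every correlated module contains
    several alternative producers; the planted signal is the hub's exclusive
    provisioning role for its dependents, not producer scarcity elsewhere.
    Quotas are proportional to unit size (largest-remainder rounding) over
    the non-hub-group units (each module, plus the background pool).
    """
    hub = ids[0]
    dependents = set(ids[1 : 1 + spec.n_dependents])
    units: dict[int, list[str]] = {}
    for g in ids:
        if g == hub or g in dependents:
            continue
        units.setdefault(module_of[g], []).append(g)
    remaining = n_prod - 1
    total = sum(len(m) for m in units.values())
    raw = {u: remaining * len(m) / total for u, m in units.items()}
    quota = {u: int(np.floor(q)) for u, q in raw.items()}
    shortfall = remaining - sum(quota.values())
    for u in sorted(units, key=lambda u: raw[u] - quota[u], reverse=True)[:shortfall]:
        quota[u] += 1
    producers = [hub]
    for u in sorted(units):
        producers += list(rng.choice(units[u], size=quota[u], replace=False))
    return producers


def _assign_roles(
    spec: SyntheticSpec,
    ids: list[str],
    module_of: dict[str, int],
    cat: PathwayCatalog,
    rng: np.random.Generator,
) -> tuple[dict, dict]:
    """Planted statuses and roles per vitamin.

    The hub is always a thiamine producer; its dependents are thiamine
    auxotrophs. Near-complete genomes (for vitamins with an exempt KO set)
    count as producers, matching the default calling policy.
    """
    statuses: dict[str, dict[str, str]] = {}
    roles: dict[str, dict[str, str]] = {}
    for vit in cat.vitamin_names:
        frac = spec.producer_fractions.get(vit, 0.5)
        n_prod = int(round(frac * spec.n_genomes))
        exempt = cat.near_complete_exempt_kos.get(vit, frozenset())
        status = {g: "absent" for g in ids}
        if vit == "thiamine":
            producers = _stratified_producers(spec, ids, module_of, n_prod, rng)
        else:
            producers = list(rng.choice(ids, size=n_prod, replace=False))
        for g in producers:
            status[g] = "complete"
        if exempt and spec.near_complete_fraction > 0:
            n_near = int(round(spec.near_complete_fraction * len(producers)))
            near = rng.choice(producers, size=n_near, replace=False)
            for g in near:
                status[g] = "near_complete"
        statuses[vit] = status
        roles[vit] = {
            g: ("producer" if status[g] != "absent" else "auxotroph") for g in ids
        }
    return statuses, roles


def simulate_community(
    spec: SyntheticSpec,
) -> tuple[AbundanceTable, SampleMetadata, SyntheticTruth]:
    """Draw one synthetic community: abundances, metadata and ground truth."""
    rng = np.random.default_rng(spec.seed)
    width = len(str(spec.n_genomes))
    ids = [f"g{i + 1:0{width}d}" for i in range(spec.n_genomes)]
    if spec.hub_id != ids[0]:
        ids[0] = spec.hub_id

    sigma, module_of = _build_correlation(spec, ids)
    chol = np.linalg.cholesky(sigma + 1e-10 * np.eye(spec.n_genomes))

    lifestyles = rng.permutation(
        ["biofilm", "planktonic"] * ((spec.n_samples + 1) // 2)
    )[: spec.n_samples]
    scn = rng.permutation(["high", "low"] * ((spec.n_samples + 1) // 2))[
        : spec.n_samples
    ]
    sample_ids = [f"s{j + 1:03d}" for j in range(spec.n_samples)]

    eps = rng.standard_normal((spec.n_samples, spec.n_genomes))
    z = spec.lognormal_mu + spec.lognormal_sigma * (eps @ chol.T)
    for j in range(spec.n_samples):
        for g_i, g in enumerate(ids):
            mod = module_of[g]
            if lifestyles[j] == "planktonic":
                z[j, g_i] += spec.lifestyle_shift.get(mod, 0.0)
            if scn[j] == "high":
                z[j, g_i] += spec.scn_shift.get(mod, 0.0)
    basis = np.exp(z)

    counts = np.empty_like(basis)
    for j in range(spec.n_samples):
        p = basis[j] / basis[j].sum()
        counts[j] = rng.multinomial(spec.depth, p)
    rel = counts / spec.depth

    tab = AbundanceTable(pd.DataFrame(rel.T, index=ids, columns=sample_ids))
    meta = SampleMetadata(
        pd.DataFrame(
            {"lifestyle": lifestyles, "scn_level": scn}, index=pd.Index(sample_ids)
        )
    )
    cat = PathwayCatalog.default()
    statuses, roles = _assign_roles(spec, ids, module_of, cat, rng)
    counts_per_genome = {
        g: sum(1 for vit in statuses if statuses[vit][g] != "absent") for g in ids
    }
    # larger genomes carry more pathways: base + per-pathway increment + noise
    lengths = {
        g: int(
            (2.5e6 + 4.0e5 * counts_per_genome[g])
            * np.exp(rng.normal(0.0, 0.1))
        )
        for g in ids
    }
    truth = SyntheticTruth(
        sigma,
        ids,
        module_of,
        roles,
        statuses,
        spec.hub_id,
        ids[1 : 1 + spec.n_dependents],
        lengths,
    )
    return tab, meta, truth


def simulate_annotations(
    truth: SyntheticTruth, cat: PathwayCatalog, spec: SyntheticSpec
) -> AnnotationSet:
    """KO sets consistent with the planted statuses under the catalog.

    Complete genomes get one KO per stage; near-complete genomes satisfy
    every non-exemptable stage and omit the exempt KOs; auxotrophs lack at
    least one non-exemptable stage entirely. Decoy KOs outside the catalog
    are sprinkled in as annotation noise.
    """
    rng = np.random.default_rng((spec.seed, 1))
    catalog_kos = frozenset().union(*(cat.all_kos(v) for v in cat.vitamin_names))
    decoys = []
    i = 90000
    while len(decoys) < spec.n_decoy_kos:
        ko = f"K{i:05d}"
        if ko not in catalog_kos:
            decoys.append(ko)
        i += 1
    kos: dict[str, set[str]] = {g: set() for g in truth.genome_ids}
    forbidden: dict[str, set[str]] = {g: set() for g in truth.genome_ids}
    # plan[(g, vit)] = (stages to satisfy, optional: bool per stage)
    plans: list[tuple[str, str, list, bool]] = []
    for vit in cat.vitamin_names:
        stages = cat.vitamins[vit]
        exempt = cat.near_complete_exempt_kos.get(vit, frozenset())
        exemptable = [s for s in stages if s.kos <= exempt]
        required = [s for s in stages if not s.kos <= exempt]
        if not exemptable and any(
            s == "near_complete" for s in truth.statuses[vit].values()
        ):
            raise ValueError(
                f"vitamin {vit!r} has near-complete genomes but no "
                "exemptable stage in the catalog"
            )
        for g in truth.genome_ids:
            status = truth.statuses[vit][g]
            if status == "complete":
                plans.append((g, vit, stages, False))
            elif status == "near_complete":
                plans.append((g, vit, required, False))
                forbidden[g].update(*(s.kos for s in exemptable))
            else:
                # drop one required stage entirely; others satisfied coin-flip
                missing_stage = required[rng.integers(len(required))]
                forbidden[g].update(missing_stage.kos)
                others = [s for s in stages if s is not missing_stage]
                plans.append((g, vit, others, True))
    for g, vit, stage_list, optional in plans:
        for s in stage_list:
            if optional and rng.random() >= 0.5:
                continue
            choices = sorted(s.kos - forbidden[g])
            if not choices:
                if optional:
                    continue
                raise ValueError(
                    f"cannot satisfy stage {s.name!r} of {vit!r} for genome "
                    f"{g!r} without breaking another planted status (KO "
                    "sharing across pathway definitions)"
                )
            kos[g].add(rng.choice(choices))
    for g in truth.genome_ids:
        n_extra = int(rng.integers(0, spec.n_decoy_kos + 1))
        kos[g].update(rng.choice(decoys, size=n_extra, replace=False))
    return AnnotationSet(
        {g: frozenset(s) for g, s in kos.items()}, dict(truth.lengths)
    )
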