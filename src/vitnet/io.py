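"""Domain types and readers/writers for every file the pipeline touches.

Tabular files are TSV (tab-delimited, UTF-8, ``#`` comment lines ignored),
matching the outputs of upstream coverage/annotation tools. Relative
abundances are stored internally as fractions in [0, 1]; percent tables are
converted on input only. Genome and sample identifiers are opaque strings.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("vitnet")

KO_PATTERN = re.compile(r"^K\d{5}$")

#: tolerance on per-sample abundance totals after normalization
SUM_TOLERANCE = 1e-6

LIFESTYLES = frozenset({"biofilm", "planktonic"})
SCN_LEVELS = frozenset({"high", "low"})


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    kwargs.setdefault("float_precision", "round_trip")
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# ---------------------------------------------------------------------------
# AbundanceTable
# ---------------------------------------------------------------------------


@dataclass
class AbundanceTable:
    """Genome x sample relative abundances (fractions in [0, 1]).

    ``values`` is a DataFrame indexed by genome id with sample-id columns.
    Genomes absent from a sample are recorded as 0, not missing.
    """

    values: pd.DataFrame
    #: permutation nulls shuffle rows independently and legitimately break
    #: the per-sample sum constraint; they construct with check_sums=False
    check_sums: bool = True

    def __post_init__(self) -> None:
        self.validate()

    @property
    def genome_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genomes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def validate(self) -> None:
        df = self.values
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValueError("abundance table is empty")
        dup = df.index[df.index.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate genome id: {dup[0]!r}")
        dup = df.columns[df.columns.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate sample id: {dup[0]!r}")
        arr = df.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite abundance at genome {df.index[i]!r}, "
                f"sample {df.columns[j]!r}"
            )
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative abundance at genome {df.index[i]!r}, "
                f"sample {df.columns[j]!r}"
            )
        sums = arr.sum(axis=0)
        bad = np.nonzero(sums > 1.0 + SUM_TOLERANCE)[0] if self.check_sums else []
        if len(bad):
            raise ValueError(
                f"column sum exceeds 1 for sample {df.columns[bad[0]]!r} "
                f"(sum={sums[bad[0]]:.6g})"
            )

    def to_tsv(self, path: str | Path) -> None:
        # repr round-trips floats exactly
        self.values.to_csv(path, sep="\t", index_label="genome_id", float_format=lambda x: repr(float(x)))

    def subset(self, genome_ids: Sequence[str]) -> "AbundanceTable":
        return AbundanceTable(self.values.loc[list(genome_ids)].copy())


def read_abundance_table(path: str | Path, unit: str = "fraction") -> AbundanceTable:
    """Read a genome x sample abundance TSV.

    Parameters
    ----------
    path
        TSV with a header row of sample ids and genome ids in the first
        column.
    unit
        ``"fraction"`` (values already in [0, 1]) or ``"percent"``
        (divided by 100 on load).
    """
    if unit not in ("fraction", "percent"):
        raise ValueError(f"unknown unit {unit!r}; expected 'fraction' or 'percent'")
    df = _read_tsv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise ValueError(f"non-numeric abundance at genome {row!r}, sample {col!r}")
        df[col] = coerced
    df = df.fillna(0.0).astype(float)
    if unit == "percent":
        df = df / 100.0
    return AbundanceTable(df)


# ---------------------------------------------------------------------------
# SampleMetadata
# ---------------------------------------------------------------------------


@dataclass
class SampleMetadata:
    """Per-sample condition labels: lifestyle (biofilm/planktonic) and
    thiocyanate level (high/low), plus free-form extra columns."""

    table: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        dup = self.table.index[self.table.index.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate sample id in metadata: {dup[0]!r}")
        if "lifestyle" in self.table.columns:
            bad = set(self.table["lifestyle"].dropna()) - LIFESTYLES
            if bad:
                raise ValueError(f"unknown lifestyle value(s): {sorted(bad)}")
        if "scn_level" in self.table.columns:
            bad = set(self.table["scn_level"].dropna()) - SCN_LEVELS
            if bad:
                raise ValueError(f"unknown scn_level value(s): {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def check_against(self, tab: AbundanceTable) -> None:
        missing = set(self.sample_ids) - set(tab.sample_ids)
        if missing:
            raise ValueError(
                f"metadata samples absent from abundance table: {sorted(missing)}"
            )

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="sample_id")


def read_sample_metadata(path: str | Path) -> SampleMetadata:
    df = _read_tsv(path, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    return SampleMetadata(df)


# ---------------------------------------------------------------------------
# AnnotationSet
# ---------------------------------------------------------------------------


@dataclass
class AnnotationSet:
    """Per-genome KEGG ortholog (KO) sets and genome lengths in bp.

    A genome may carry an empty KO set. Genomes with annotations but no
    recorded length are kept; they are excluded from size analyses only.
    """

    kos: dict[str, frozenset[str]]
    lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for genome, koset in self.kos.items():
            for ko in koset:
                if not KO_PATTERN.match(ko):
                    raise ValueError(
                        f"malformed KO id {ko!r} for genome {genome!r} "
                        "(expected K followed by five digits)"
                    )
        for genome, length in self.lengths.items():
            if not (isinstance(length, (int, np.integer)) and length > 0):
                raise ValueError(
                    f"genome length must be a positive integer; got "
                    f"{length!r} for {genome!r}"
                )

    @property
    def genome_ids(self) -> list[str]:
        return list(self.kos)

    def to_tsv(self, ko_path: str | Path, lengths_path: str | Path | None = None) -> None:
        with open(ko_path, "w") as fh:
            fh.write("genome_id\tko_id\n")
            for genome, koset in self.kos.items():
                for ko in sorted(koset):
                    fh.write(f"{genome}\t{ko}\n")
        if lengths_path is not None:
            with open(lengths_path, "w") as fh:
                fh.write("genome_id\tlength_bp\n")
                for genome, length in self.lengths.items():
                    fh.write(f"{genome}\t{length}\n")


def read_annotations(
    path: str | Path,
    lengths_path: str | Path | None = None,
    genome_ids: Iterable[str] | None = None,
) -> AnnotationSet:
    """Read long-format genome->KO annotations plus an optional length table.

    ``genome_ids`` lists genomes that must appear even with an empty KO set.
    """
    df = _read_tsv(path, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("annotation TSV needs columns genome_id, ko_id")
    gcol, kcol = df.columns[:2]
    kos: dict[str, set[str]] = {}
    for genome, ko in zip(df[gcol].astype(str), df[kcol].astype(str)):
        kos.setdefault(genome, set()).add(ko)
    if genome_ids is not None:
        for g in genome_ids:
            kos.setdefault(str(g), set())
    lengths: dict[str, int] = {}
    if lengths_path is not None:
        ldf = _read_tsv(lengths_path)
        lg, ll = ldf.columns[:2]
        for genome, length in zip(ldf[lg].astype(str), ldf[ll]):
            lengths[genome] = int(length)
        no_length = set(kos) - set(lengths)
        if no_length:
            logger.warning(
                "EXCLUDED_FROM_SIZE_ANALYSES\t%d genome(s) annotated but "
                "lacking a length: %s",
                len(no_length),
                ",".join(sorted(no_length)[:10]),
            )
    return AnnotationSet({g: frozenset(s) for g, s in kos.items()}, lengths)


# ---------------------------------------------------------------------------
# PathwayCatalog
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PathwayStage:
    name: str
    kos: frozenset[str]


@dataclass
class PathwayCatalog:
    """Vitamin biosynthesis pathway definitions.

    Each vitamin is an ordered list of stages; a stage is satisfied by any
    one of its alternative KOs. ``near_complete_exempt_kos`` lists KOs whose
    sole absence still yields near-complete status (for thiamine:
    phosphomethylpyrimidine synthase thiC, K03147).
    """

    vitamins: dict[str, list[PathwayStage]]
    near_complete_exempt_kos: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for vit, stages in self.vitamins.items():
            if not stages:
                raise ValueError(f"vitamin {vit!r} has no stages")
            union: set[str] = set()
            for stage in stages:
                if not stage.kos:
                    raise ValueError(
                        f"stage {stage.name!r} of vitamin {vit!r} has no KOs"
                    )
                for ko in stage.kos:
                    if not KO_PATTERN.match(ko):
                        raise ValueError(f"malformed KO id {ko!r} in catalog")
                union |= stage.kos
            exempt = self.near_complete_exempt_kos.get(vit, frozenset())
            if not exempt <= union:
                raise ValueError(
                    f"exempt KOs {sorted(exempt - union)} of vitamin {vit!r} "
                    "are not part of any stage"
                )

    @property
    def vitamin_names(self) -> list[str]:
        return list(self.vitamins)

    def stage_names(self, vitamin: str) -> list[str]:
        return [s.name for s in self.vitamins[vitamin]]

    def all_kos(self, vitamin: str) -> frozenset[str]:
        return frozenset().union(*(s.kos for s in self.vitamins[vitamin]))

    @classmethod
    def from_dict(cls, data: Mapping) -> "PathwayCatalog":
        vitamins = {}
        exempt = {}
        for vit, spec in data.items():
            vitamins[vit] = [
                PathwayStage(stage["name"], frozenset(stage["kos"]))
                for stage in spec["stages"]
            ]
            exempt[vit] = frozenset(spec.get("near_complete_exempt_kos", []))
        return cls(vitamins, exempt)

    def to_dict(self) -> dict:
        return {
            vit: {
                "stages": [
                    {"name": s.name, "kos": sorted(s.kos)} for s in stages
                ],
                "near_complete_exempt_kos": sorted(
                    self.near_complete_exempt_kos.get(vit, frozenset())
                ),
            }
            for vit, stages in self.vitamins.items()
        }

    @classmethod
    def from_json(cls, path: str | Path) -> "PathwayCatalog":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def default(cls) -> "PathwayCatalog":
        """The shipped catalog: thiamine, biotin, tetrahydrofolate,
        riboflavin, NAD and pantothenate."""
        ref = resources.files("vitnet") / "data" / "pathway_catalog.json"
        return cls.from_dict(json.loads(ref.read_text()))


# ---------------------------------------------------------------------------
# CorrelationMatrix
# ---------------------------------------------------------------------------


@dataclass
class CorrelationMatrix:
    """Symmetric pairwise correlations with unit diagonal, optionally with
    permutation p-values."""

    genome_ids: list[str]
    r: np.ndarray
    p: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genome_ids = list(self.genome_ids)
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.genome_ids)
        if self.r.shape != (n, n):
            raise ValueError(f"r has shape {self.r.shape}, expected ({n}, {n})")
        if not np.allclose(self.r, self.r.T, atol=0, rtol=0):
            raise ValueError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0):
            raise ValueError("correlation matrix diagonal is not 1")
        if np.nanmax(np.abs(self.r)) > 1 + 1e-12:
            raise ValueError("correlation values outside [-1, 1]")
        if self.p is not None:
            self.p = np.asarray(self.p, dtype=float)
            if self.p.shape != (n, n):
                raise ValueError("p-value matrix shape mismatch")
            if (self.p < 0).any() or (self.p > 1).any():
                raise ValueError("p-values outside [0, 1]")

    @property
    def n(self) -> int:
        return len(self.genome_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.genome_ids, columns=self.genome_ids)


def read_correlation_matrix(
    path: str | Path, pvals_path: str | Path | None = None
) -> CorrelationMatrix:
    df = _read_tsv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ValueError("correlation matrix rows and columns disagree")
    p = None
    if pvals_path is not None:
        pdf = _read_tsv(pvals_path, index_col=0)
        p = pdf.to_numpy(dtype=float)
    return CorrelationMatrix(list(df.index), df.to_numpy(dtype=float), p)


def write_correlation_matrix(
    corr: CorrelationMatrix, path: str | Path, pvals_path: str | Path | None = None
) -> None:
    corr.to_frame().to_csv(path, sep="\t", index_label="genome_id", float_format=lambda x: repr(float(x)))
    if pvals_path is not None and corr.p is not None:
        pd.DataFrame(corr.p, index=corr.genome_ids, columns=corr.genome_ids).to_csv(
            pvals_path, sep="\t", index_label="genome_id", float_format=lambda x: repr(float(x))
        )


# ---------------------------------------------------------------------------
# CooccurrenceNetwork (networkx.Graph with 'weight' edge attribute)
# ---------------------------------------------------------------------------


def write_network(net: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Write the co-occurrence network as GraphML (Cytoscape-importable) or
    as a three-column edge TSV (each undirected edge once)."""
    if format == "graphml":
        nx.write_graphml(net, path)
    elif format == "edge_tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tweight\n")
            for u, v, w in net.edges(data="weight", default=1.0):
                fh.write(f"{u}\t{v}\t{w!r}\n")
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | Path, format: str = "graphml") -> nx.Graph:
    if format == "graphml":
        return nx.read_graphml(path)
    if format == "edge_tsv":
        df = _read_tsv(path)
        g = nx.Graph()
        for u, v, w in zip(df["source"].astype(str), df["target"].astype(str), df["weight"]):
            g.add_edge(u, v, weight=float(w))
        return g
    raise ValueError(f"unknown network format {format!r}")
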