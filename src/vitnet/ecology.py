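"""Condition-stratified prevalence and abundance comparisons.

Samples are split along a binary metadata axis (biofilm vs planktonic
lifestyle, or high vs low thiocyanate) and each entity — a single genome or
a module aggregate (sum of member abundances per sample) — is compared
between the two categories: presence frequency, mean relative abundance, and
Welch's two-sided t-test on the per-sample abundances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from vitnet.io import AbundanceTable, SampleMetadata


@dataclass
class CategoryComparison:
    entity: str
    axis: str
    per_category: dict[str, dict]  # category -> {n, frequency, mean_abundance}
    welch_t: float | None
    p_two_sided: float | None


def compare_categories(
    tab: AbundanceTable,
    meta: SampleMetadata,
    axis: str,
    entities: Mapping[str, Sequence[str]] | Sequence[str],
    presence_threshold: float = 0.0,
) -> list[CategoryComparison]:
    """Compare entity abundances between the two categories of an axis.

    ``entities`` maps entity name to its member genomes (a bare sequence of
    genome ids is treated as singleton entities). Frequency is the fraction
    of category samples where the entity's abundance exceeds
    ``presence_threshold`` (default 0: any detection counts). The t statistic
    is computed as first category minus second, categories in sorted order;
    a category with fewer than 2 samples makes the test not-computable.
    """
    if not isinstance(entities, Mapping):
        entities = {str(e): [str(e)] for e in entities}
    if axis not in meta.table.columns:
        raise KeyError(f"axis {axis!r} not in sample metadata")
    meta.check_against(tab)
    labels = meta.table[axis].dropna()
    cats = sorted(set(labels))
    if len(cats) != 2:
        raise ValueError(
            f"axis {axis!r} must have exactly 2 categories, found {cats}"
        )
    groups = {c: [s for s in labels.index if labels[s] == c] for c in cats}

    out: list[CategoryComparison] = []
    for name, members in entities.items():
        missing = set(members) - set(tab.genome_ids)
        if missing:
            raise KeyError(f"entity {name!r} members not in table: {sorted(missing)}")
        profile = tab.values.loc[list(members)].sum(axis=0)
        per_cat = {}
        vectors = {}
        for c in cats:
            vals = profile[groups[c]].to_numpy(dtype=float)
            vectors[c] = vals
            per_cat[c] = {
                "n": len(vals),
                "frequency": float((vals > presence_threshold).mean())
                if len(vals)
                else None,
                "mean_abundance": float(vals.mean()) if len(vals) else None,
            }
        a, b = vectors[cats[0]], vectors[cats[1]]
        if len(a) < 2 or len(b) < 2:
            t = p = None
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
            if np.isnan(t):
                t = p = None
            else:
                t, p = float(t), float(p)
        out.append(CategoryComparison(name, axis, per_cat, t, p))
    return out
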