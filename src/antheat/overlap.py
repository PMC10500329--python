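"""Cross-species comparison of differential transcripts by annotation name.

Differential transcript lists are reduced to unique, meaningful annotation
names (dropping "uncharacterized protein" entries and case-insensitive
duplicates); pairwise overlaps are tested against a Monte-Carlo null that
redraws the same number of transcripts from each species' full transcriptome
and reduces them the same way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

UNCHARACTERIZED = "uncharacterized protein"


@dataclass
class NameSet:
    species_id: str
    names: frozenset[str]
    source_size: int  # transcripts the set was reduced from

    def __len__(self) -> int:
        return len(self.names)


@dataclass
class OverlapTest:
    species_a: str
    species_b: str
    observed: int
    null_mean: float
    null_sd: float
    iterations: int
    seed: int
    p: float
    alpha: float = 0.01

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


def _normalize_name(name) -> str | None:
    """Trim + casefold; None for unannotated or uncharacterized entries."""
    if not isinstance(name, str):
        return None
    name = name.strip()
    if not name:
        return None
    low = name.casefold()
    if UNCHARACTERIZED in low:
        return None
    return low


def unique_meaningful_names(
    catalog: pd.Series, subset=None, species_id: str = ""
) -> NameSet:
    """Reduce transcripts to their unique, meaningful annotation names.

    `catalog` maps transcript id -> annotation string.  Unannotated entries
    and annotations containing "uncharacterized protein" are dropped; names
    are compared after trimming and case-folding.
    """
    if subset is None:
        subset = catalog.index
    else:
        subset = pd.Index(subset)
        missing = subset.difference(catalog.index)
        if len(missing):
            raise KeyError(f"transcripts not in catalog: {list(missing[:5])}...")
    names = {
        norm
        for tid in subset
        if (norm := _normalize_name(catalog[tid])) is not None
    }
    return NameSet(species_id=species_id, names=frozenset(names),
                   source_size=len(subset))


def observed_overlap(set_a: NameSet, set_b: NameSet) -> int:
    """Number of annotation names shared by the two sets."""
    return len(set_a.names & set_b.names)


def _name_codes(catalog: pd.Series) -> tuple[np.ndarray, dict[str, int]]:
    """Per-transcript integer name codes; -1 marks non-meaningful entries."""
    codes = np.full(len(catalog), -1, dtype=np.int64)
    table: dict[str, int] = {}
    for i, ann in enumerate(catalog.to_numpy()):
        norm = _normalize_name(ann)
        if norm is None:
            continue
        codes[i] = table.setdefault(norm, len(table))
    return codes, table


def resampling_null(
    catalog_a: pd.Series,
    catalog_b: pd.Series,
    n_a: int,
    n_b: int,
    iterations: int = 10000,
    seed: int = 0,
    species_a: str = "A",
    species_b: str = "B",
    observed: int | None = None,
    alpha: float = 0.01,
) -> OverlapTest:
    """Monte-Carlo null for the shared-name count between two DET lists.

    Each iteration draws n_a transcripts without replacement from species A's
    full transcriptome and n_b from species B's, reduces both to unique
    meaningful names, and records the overlap.  The empirical p-value uses
    the (1 + exceedances) / (iterations + 1) estimator so it is never zero.
    """
    if n_a > len(catalog_a) or n_b > len(catalog_b):
        raise ValueError("requested sample exceeds catalog size")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")

    if observed is None:
        raise ValueError("observed overlap count is required")

    codes_a, table_a = _name_codes(catalog_a)
    codes_b, table_b = _name_codes(catalog_b)
    shared = sorted(set(table_a) & set(table_b))
    # one stream per species, keyed by sorted species id, so swapping the
    # two catalogs (with their labels) reproduces the identical null draws
    children = np.random.SeedSequence(seed).spawn(2)
    stream = dict(zip(sorted([species_a, species_b]), children))
    rng_a = np.random.default_rng(stream[species_a])
    rng_b = np.random.default_rng(stream[species_b])
    nulls = np.zeros(iterations, dtype=np.int64)
    if shared:
        shared_idx = {name: i for i, name in enumerate(shared)}
        # per-transcript index into the shared-name list (-1: not shared)
        map_a = np.full(len(catalog_a), -1, dtype=np.int64)
        map_b = np.full(len(catalog_b), -1, dtype=np.int64)
        rev_a = {v: k for k, v in table_a.items()}
        rev_b = {v: k for k, v in table_b.items()}
        for i, c in enumerate(codes_a):
            if c >= 0 and rev_a[c] in shared_idx:
                map_a[i] = shared_idx[rev_a[c]]
        for i, c in enumerate(codes_b):
            if c >= 0 and rev_b[c] in shared_idx:
                map_b[i] = shared_idx[rev_b[c]]
        n_shared = len(shared)
        for it in range(iterations):
            draw_a = map_a[rng_a.choice(len(catalog_a), size=n_a, replace=False)]
            draw_b = map_b[rng_b.choice(len(catalog_b), size=n_b, replace=False)]
            present_a = np.zeros(n_shared, dtype=bool)
            present_a[draw_a[draw_a >= 0]] = True
            present_b = np.zeros(n_shared, dtype=bool)
            present_b[draw_b[draw_b >= 0]] = True
            nulls[it] = int(np.count_nonzero(present_a & present_b))

    p = (1.0 + int(np.count_nonzero(nulls >= observed))) / (iterations + 1.0)
    return OverlapTest(
        species_a=species_a,
        species_b=species_b,
        observed=observed,
        null_mean=float(nulls.mean()),
        null_sd=float(nulls.std(ddof=1)) if iterations > 1 else 0.0,
        iterations=iterations,
        seed=seed,
        p=p,
        alpha=alpha,
    )


def correlate_size_det(sizes, det_counts) -> CorrelationResult:
    """Pearson correlation between transcriptome size and DET count."""
    x = np.asarray(sizes, dtype=float)
    y = np.asarray(det_counts, dtype=float)
    if x.shape != y.shape:
        raise ValueError("sizes and det_counts must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=int(x.size))


def det_percentage(det_count: int, transcriptome_size: int) -> tuple[float, float]:
    """DET share of the transcriptome in percent: (unrounded, 2-decimal)."""
    if transcriptome_size <= 0:
        raise ValueError("transcriptome size must be positive")
    pct = 100.0 * det_count / transcriptome_size
    return pct, round(pct, 2)
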