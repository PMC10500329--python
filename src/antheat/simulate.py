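"""Synthetic multi-species heat-stress studies with known ground truth.

The default study emulates a six-species ant design: four desert species
(two keeping constitutively high chaperone expression, two inducing it
reactively) and two temperate species with broad heat-stress responses.
Every generator is seeded; one master seed deterministically derives one
child seed per stage (survival, transcriptomes, orthogroups, counts in
species order) via numpy's SeedSequence spawning, so stages can be
regenerated independently.

Emitted objects use exactly the containers and file formats the readers in
:mod:`antheat.io` consume, plus a ground-truth record for tests.  An audit
pass re-derives the ground truth from the emitted objects on every run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import CountMatrix
from .orthology import OrthogroupTable, SpeciesMeta
from .overlap import UNCHARACTERIZED, _normalize_name
from .thermal import SurvivalObservation

DEFAULT_TEMPERATURES = (39.0, 41.0, 43.0, 45.0, 47.0, 49.0, 51.0)

STRATEGIES = ("constitutive", "reactive", "temperate_like")

#: heat-shock protein names seeded into the shared annotation pool so every
#: species catalog contains HSP70/HSP90 isoforms
HSP_NAMES = (
    "heat shock protein 70 cognate 4",
    "heat shock protein 70 A1-like",
    "hsp70 isoform X2",
    "heat shock protein 70 Bbb",
    "heat shock protein 90 alpha",
    "hsp90 isoform X1",
    "heat shock protein 90 beta-like",
)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SpeciesSimSpec:
    """Everything needed to simulate one species of the study."""

    species_id: str
    true_lt50: float  # degC
    logit_slope: float  # per degC, > 0: death increases with temperature
    transcriptome_size: int
    unique_name_count: int
    shared_pool_fraction: float  # share of names drawn from the cross-species pool
    uncharacterized_fraction: float  # share of transcripts with no meaningful name
    strategy: str
    n_stress_genes: int
    induced_log2fc: float
    baseline_meanlog: float = 4.0
    baseline_sdlog: float = 1.5
    stress_meanlog: float = 5.5  # stress genes are well-expressed chaperone-like
    stress_sdlog: float = 0.8
    constitutive_lift: float = 2.0  # added to meanlog for constitutive stress genes
    dispersion: float = 0.1
    down_fraction: float = 0.3  # induced genes that go down rather than up in HS

    def __post_init__(self) -> None:
        if self.logit_slope <= 0:
            raise SimulationError("logit_slope must be positive")
        for frac in (self.shared_pool_fraction, self.uncharacterized_fraction,
                     self.down_fraction):
            if not 0.0 <= frac <= 1.0:
                raise SimulationError("fractions must lie in [0, 1]")
        if self.transcriptome_size < self.unique_name_count:
            raise SimulationError("transcriptome_size must be >= unique_name_count")
        if self.induced_log2fc < 0:
            raise SimulationError("induced_log2fc must be >= 0")
        if self.strategy not in STRATEGIES:
            raise SimulationError(f"unknown strategy {self.strategy!r}")
        if self.dispersion <= 0:
            raise SimulationError("dispersion must be positive")


def _spec(sid, lt50, slope, size, strategy, n_stress, fc) -> SpeciesSimSpec:
    return SpeciesSimSpec(
        species_id=sid,
        true_lt50=lt50,
        logit_slope=slope,
        transcriptome_size=size,
        unique_name_count=int(round(size * 0.55)),
        shared_pool_fraction=0.7,
        uncharacterized_fraction=0.25,
        strategy=strategy,
        n_stress_genes=n_stress,
        induced_log2fc=fc,
    )


#: the default six-species study at ~1/20 transcriptome scale: LT50s and
#: transcriptome proportions mirror the assay design (7 temperatures x 6
#: tubes x 10 workers, 4+4 replicates); slope 5/degC gives the abrupt
#: two-degree survival crash with ~99% survival one 2-degree grid step below
#: the LT50 (so the upper thermal limit lands one step below the LT50, as
#: the steep-decline species show), slope 1/degC the gradual six-degree
#: decline
DEFAULT_SPECS: tuple[SpeciesSimSpec, ...] = (
    _spec("Cbom", 44.83, 1.0, 2096, "reactive", 13, 3.0),
    _spec("Chol", 46.00, 5.0, 2226, "constitutive", 50, 0.0),
    _spec("Mbag", 49.83, 5.0, 1936, "constitutive", 50, 0.0),
    _spec("Orob", 46.80, 1.0, 2285, "reactive", 35, 3.0),
    _spec("Ffus", 42.00, 5.0, 3121, "temperate_like", 250, 3.0),
    _spec("Msab", 39.91, 5.0, 4239, "temperate_like", 540, 3.0),
)

DEFAULT_SPECIES_META: tuple[SpeciesMeta, ...] = (
    SpeciesMeta("Cbom", "Formicinae", "Cataglyphis", "desert"),
    SpeciesMeta("Chol", "Formicinae", "Cataglyphis", "desert"),
    SpeciesMeta("Mbag", "Formicinae", "Melophorus", "desert"),
    SpeciesMeta("Orob", "Myrmicinae", "Ocymyrmex", "desert"),
    SpeciesMeta("Ffus", "Formicinae", "Formica", "temperate"),
    SpeciesMeta("Msab", "Myrmicinae", "Myrmica", "temperate"),
)

#: orthogroup category mixture shaped after a six-species transcriptomic
#: orthology run (categories I..V plus cross-subfamily partial orthogroups)
DEFAULT_CATEGORY_MIXTURE: dict[str, float] = {
    "I": 0.26, "II": 0.03, "III": 0.01, "IV": 0.026, "V": 0.269, "mixed": 0.405,
}


def logistic(x) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def death_probability(spec: SpeciesSimSpec, temperature) -> np.ndarray:
    """True death probability at a temperature for this species."""
    return logistic(spec.logit_slope * (np.asarray(temperature, float) - spec.true_lt50))


# ---------------------------------------------------------------------------
# survival


def simulate_survival(
    spec: SpeciesSimSpec,
    temperatures=DEFAULT_TEMPERATURES,
    tubes_per_temp: int = 6,
    workers_per_tube: int = 10,
    seed: int | np.random.SeedSequence = 0,
) -> list[SurvivalObservation]:
    """Binomial tube-level deaths around the species' true dose-response curve."""
    if workers_per_tube <= 0:
        raise SimulationError("workers_per_tube must be positive")
    if len(temperatures) == 0:
        raise SimulationError("need at least one temperature")
    rng = np.random.default_rng(seed)
    out = []
    for t in temperatures:
        p = float(death_probability(spec, t))
        deaths = rng.binomial(workers_per_tube, p, size=tubes_per_temp)
        for tube, d in enumerate(deaths, start=1):
            out.append(
                SurvivalObservation(
                    species_id=spec.species_id,
                    temperature=float(t),
                    tube_id=str(tube),
                    n_total=workers_per_tube,
                    n_dead=int(d),
                )
            )
    return out


# ---------------------------------------------------------------------------
# annotation catalogs


def _shared_pool(shared_pool_size: int) -> list[str]:
    if shared_pool_size < 1:
        raise SimulationError("shared_pool_size must be >= 1")
    pool = list(HSP_NAMES[: min(len(HSP_NAMES), shared_pool_size)])
    pool += [f"conserved protein {i:05d}" for i in range(shared_pool_size - len(pool))]
    return pool


def simulate_transcriptomes(
    specs,
    shared_pool_size: int = 3000,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[dict[str, pd.Series], dict[tuple[str, str], int]]:
    """Per-species annotation catalogs with a cross-species shared name pool.

    Each catalog has `transcriptome_size` rows: the species' unique names
    (partly drawn from the shared pool, partly species-private), replicated
    over extra transcripts to mimic isoform redundancy, plus a fraction of
    "uncharacterized protein" entries.  Returns the catalogs and the true
    pairwise shared-name counts.
    """
    pool = _shared_pool(shared_pool_size)
    rng = np.random.default_rng(seed)
    catalogs: dict[str, pd.Series] = {}
    shared_names: dict[str, set[str]] = {}
    loc_counter = 10000000
    for spec in specs:
        n_names = spec.unique_name_count
        n_shared = int(round(spec.shared_pool_fraction * n_names))
        n_private = n_names - n_shared
        if n_shared > len(pool):
            raise SimulationError(
                f"{spec.species_id}: requested {n_shared} shared names but the "
                f"pool holds only {len(pool)}"
            )
        n_unchar = int(round(spec.uncharacterized_fraction * spec.transcriptome_size))
        n_meaningful_rows = spec.transcriptome_size - n_unchar
        if n_names > n_meaningful_rows:
            raise SimulationError(
                f"{spec.species_id}: {n_names} unique names do not fit in "
                f"{n_meaningful_rows} meaningful rows"
            )
        # always include the HSP names so every species has chaperone isoforms
        n_hsp = min(len(HSP_NAMES), n_shared)
        rest = rng.choice(len(pool) - n_hsp, size=n_shared - n_hsp, replace=False)
        drawn_shared = pool[:n_hsp] + [pool[n_hsp + i] for i in sorted(rest)]
        private = [
            f"{spec.species_id} specific protein {i:05d}" for i in range(n_private)
        ]
        names = drawn_shared + private
        # every unique name at least once; the rest are redundant isoforms
        extra = rng.choice(n_names, size=n_meaningful_rows - n_names, replace=True)
        annotations = names + [names[i] for i in extra]
        for _ in range(n_unchar):
            annotations.append(f"{UNCHARACTERIZED} LOC{loc_counter}")
            loc_counter += 1
        order = rng.permutation(spec.transcriptome_size)
        tids = [f"{spec.species_id}_T{i:06d}" for i in range(spec.transcriptome_size)]
        catalogs[spec.species_id] = pd.Series(
            [annotations[j] for j in order], index=tids, name="annotation"
        )
        shared_names[spec.species_id] = {n.casefold() for n in drawn_shared}

    truth = {}
    sids = [s.species_id for s in specs]
    for i, a in enumerate(sids):
        for b in sids[i + 1:]:
            truth[(a, b)] = len(shared_names[a] & shared_names[b])
    return catalogs, truth


# ---------------------------------------------------------------------------
# orthogroups


def _mixture_counts(mixture: dict[str, float], n: int) -> dict[str, int]:
    keys = list(mixture)
    if abs(sum(mixture.values()) - 1.0) > 1e-9:
        raise SimulationError("category mixture must sum to 1")
    raw = {k: mixture[k] * n for k in keys}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    for k in sorted(keys, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def simulate_orthogroups(
    catalogs: dict[str, pd.Series],
    species_meta: dict[str, SpeciesMeta],
    category_mixture: dict[str, float] | None = None,
    n_orthogroups: int = 1200,
    extra_genes_mean: float = 0.3,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[OrthogroupTable, dict[str, str]]:
    """Emit an orthogroup table whose species-presence patterns realize a
    requested category mixture; gene ids are consumed from the catalogs
    without reuse (leftover genes stay unassigned, as in real orthology runs).
    """
    mixture = dict(category_mixture or DEFAULT_CATEGORY_MIXTURE)
    unknown = set(mixture) - {"I", "II", "III", "IV", "V", "mixed"}
    if unknown:
        raise SimulationError(f"unknown mixture categories {sorted(unknown)}")
    sids = list(catalogs)
    myrm = [s for s in sids if species_meta[s].subfamily == "Myrmicinae"]
    form = [s for s in sids if species_meta[s].subfamily == "Formicinae"]
    genus_pairs = {}
    for s in sids:
        genus_pairs.setdefault(species_meta[s].genus, []).append(s)
    same_genus = [v for v in genus_pairs.values() if len(v) >= 2]
    if mixture.get("IV", 0) > 0 and not same_genus:
        raise SimulationError(
            "mixture requests category IV but no genus has two or more species"
        )
    if mixture.get("II", 0) > 0 and len(myrm) < 2:
        raise SimulationError("category II needs >= 2 Myrmicinae species")
    if mixture.get("III", 0) > 0 and len(form) < 2:
        raise SimulationError("category III needs >= 2 Formicinae species")

    rng = np.random.default_rng(seed)
    pools = {
        s: list(rng.permutation(np.asarray(catalogs[s].index))) for s in sids
    }

    def take(sp: str, k: int) -> list[str]:
        if len(pools[sp]) < k:
            raise SimulationError(f"species {sp} ran out of unassigned genes")
        out = pools[sp][-k:]
        del pools[sp][-k:]
        return out

    def pick_presence(cat: str) -> list[str]:
        if cat == "I":
            return sids
        if cat == "II":
            return myrm
        if cat == "III":
            for _ in range(100):
                k = int(rng.integers(2, len(form) + 1))
                chosen = [form[i] for i in rng.choice(len(form), k, replace=False)]
                genera = {species_meta[s].genus for s in chosen}
                if len(genera) >= 2:
                    return chosen
            raise SimulationError("could not draw a multi-genus Formicinae subset")
        if cat == "IV":
            group = same_genus[int(rng.integers(len(same_genus)))]
            return group[:2]
        if cat == "V":
            return [sids[int(rng.integers(len(sids)))]]
        # mixed: spans both subfamilies but misses at least one species
        for _ in range(100):
            k = int(rng.integers(2, len(sids)))
            chosen = [sids[i] for i in rng.choice(len(sids), k, replace=False)]
            subfams = {species_meta[s].subfamily for s in chosen}
            if len(subfams) == 2:
                return chosen
        raise SimulationError("could not draw a mixed-subfamily subset")

    counts = _mixture_counts(mixture, n_orthogroups)
    members: dict[str, dict[str, list[str]]] = {}
    truth: dict[str, str] = {}
    og_idx = 0
    for cat in ("I", "II", "III", "IV", "V", "mixed"):
        for _ in range(counts.get(cat, 0)):
            og = f"OG{og_idx:07d}"
            og_idx += 1
            present = pick_presence(cat)
            members[og] = {
                sp: take(sp, 1 + int(rng.poisson(extra_genes_mean)))
                for sp in present
            }
            truth[og] = "mixed_partial" if cat == "mixed" else cat
    table = OrthogroupTable(members=members, species=sids)
    return table, truth


# ---------------------------------------------------------------------------
# counts


def _matches_hsp(annotation: str) -> bool:
    low = annotation.lower() if isinstance(annotation, str) else ""
    return any(term in low for term in ("hsp70", "hsp 70", "heat shock protein 70",
                                        "hsp90", "hsp 90", "heat shock protein 90"))


def choose_stress_genes(spec: SpeciesSimSpec, catalog: pd.Series,
                        rng: np.random.Generator) -> list[str]:
    """Stress genes are the HSP-annotated transcripts first, topped up with
    other meaningfully annotated transcripts."""
    hsp = [t for t, a in catalog.items() if _matches_hsp(a)]
    if len(hsp) >= spec.n_stress_genes:
        return hsp[: spec.n_stress_genes]
    meaningful = [
        t for t, a in catalog.items()
        if _normalize_name(a) is not None and not _matches_hsp(a)
    ]
    extra_n = spec.n_stress_genes - len(hsp)
    extra = [meaningful[i] for i in rng.choice(len(meaningful), extra_n, replace=False)]
    return hsp + extra


def simulate_counts(
    spec: SpeciesSimSpec,
    catalog: pd.Series,
    reps_per_condition: int = 4,
    seed: int | np.random.SeedSequence = 0,
    stress_genes: list[str] | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Negative-binomial counts with the species' stress-gene archetype.

    Baseline means are log-normal; reactive/temperate stress genes get HS
    means shifted by 2**induced_log2fc (a `down_fraction` of them shifted
    down instead); constitutive stress genes get means lifted in BOTH
    conditions and no shift.  Library sizes vary uniformly within +-30%.
    Returns the count matrix and a per-transcript truth table.
    """
    if reps_per_condition < 2:
        raise SimulationError("need at least two replicates per condition")
    rng = np.random.default_rng(seed)
    tids = list(catalog.index)
    size = len(tids)
    if stress_genes is None:
        stress_genes = choose_stress_genes(spec, catalog, rng)
    stress_idx = pd.Index(tids).get_indexer(stress_genes)
    if (stress_idx < 0).any():
        raise SimulationError("stress gene absent from catalog")

    mu = rng.lognormal(spec.baseline_meanlog, spec.baseline_sdlog, size)
    true_fc = np.zeros(size)
    constitutive = np.zeros(size, dtype=bool)
    if spec.strategy == "constitutive":
        mu[stress_idx] = rng.lognormal(
            spec.baseline_meanlog + spec.constitutive_lift, spec.stress_sdlog,
            len(stress_idx),
        )
        constitutive[stress_idx] = True
        hs_mu = mu.copy()
    else:
        mu[stress_idx] = rng.lognormal(
            spec.stress_meanlog, spec.stress_sdlog, len(stress_idx)
        )
        down = rng.random(len(stress_idx)) < spec.down_fraction
        fc = np.where(down, -spec.induced_log2fc, spec.induced_log2fc)
        true_fc[stress_idx] = fc
        hs_mu = mu.copy()
        hs_mu[stress_idx] = mu[stress_idx] * 2.0 ** fc

    samples = [f"{spec.species_id}_HS_{r+1}" for r in range(reps_per_condition)] + [
        f"{spec.species_id}_NHS_{r+1}" for r in range(reps_per_condition)
    ]
    conditions = pd.Series(
        ["HS"] * reps_per_condition + ["NHS"] * reps_per_condition, index=samples
    )
    lib_factors = rng.uniform(0.7, 1.3, len(samples))
    n_nb = 1.0 / spec.dispersion
    mat = np.empty((size, len(samples)), dtype=np.int64)
    for j, sample in enumerate(samples):
        mean = (hs_mu if conditions[sample] == "HS" else mu) * lib_factors[j]
        p = n_nb / (n_nb + mean)
        mat[:, j] = rng.negative_binomial(n_nb, p)

    counts = CountMatrix(
        counts=pd.DataFrame(mat, index=tids, columns=samples),
        conditions=conditions,
    )
    truth = pd.DataFrame(
        {
            "transcript_id": tids,
            "true_de": true_fc != 0,
            "true_log2fc": true_fc,
            "stress_gene": np.isin(np.arange(size), stress_idx),
            "constitutive": constitutive,
            "nhs_mean": mu,
            "hs_mean": hs_mu,
        }
    ).set_index("transcript_id")
    return counts, truth


# ---------------------------------------------------------------------------
# whole studies


@dataclass
class GroundTruth:
    lt50: dict[str, float]
    slope: dict[str, float]
    strategy: dict[str, str]
    de: dict[str, pd.DataFrame]  # species -> per-transcript truth table
    shared_names: dict[tuple[str, str], int]
    og_category: dict[str, str]
    stress_genes: dict[str, list[str]]


@dataclass
class StudyData:
    specs: dict[str, SpeciesSimSpec]
    species_meta: dict[str, SpeciesMeta]
    survival: list[SurvivalObservation]
    catalogs: dict[str, pd.Series]
    counts: dict[str, CountMatrix]
    orthogroups: OrthogroupTable
    truth: GroundTruth
    master_seed: int


def simulate_study(
    seed: int = 0,
    specs=DEFAULT_SPECS,
    species_meta=DEFAULT_SPECIES_META,
    temperatures=DEFAULT_TEMPERATURES,
    tubes_per_temp: int = 6,
    workers_per_tube: int = 10,
    reps_per_condition: int = 4,
    shared_pool_size: int = 3000,
    category_mixture: dict[str, float] | None = None,
    n_orthogroups: int = 1200,
    audit: bool = True,
) -> StudyData:
    """Generate a complete study: survival assays, annotation catalogs,
    orthogroups, and count matrices, with a consistent ground-truth record.

    Child seeds are spawned from the master seed in a fixed order:
    [survival per species, transcriptomes, orthogroups, counts per species].
    """
    specs = list(specs)
    meta = {m.species_id: m for m in species_meta}
    n_sp = len(specs)
    children = np.random.SeedSequence(seed).spawn(2 * n_sp + 2)
    surv_seeds = children[:n_sp]
    tr_seed = children[n_sp]
    og_seed = children[n_sp + 1]
    count_seeds = children[n_sp + 2:]

    survival: list[SurvivalObservation] = []
    for sp, ss in zip(specs, surv_seeds):
        survival.extend(
            simulate_survival(sp, temperatures, tubes_per_temp, workers_per_tube, ss)
        )

    catalogs, shared_truth = simulate_transcriptomes(specs, shared_pool_size, tr_seed)
    og_table, og_truth = simulate_orthogroups(
        catalogs, meta, category_mixture, n_orthogroups, seed=og_seed
    )

    counts: dict[str, CountMatrix] = {}
    de_truth: dict[str, pd.DataFrame] = {}
    stress: dict[str, list[str]] = {}
    for sp, cs in zip(specs, count_seeds):
        cm, tr = simulate_counts(sp, catalogs[sp.species_id], reps_per_condition, cs)
        counts[sp.species_id] = cm
        de_truth[sp.species_id] = tr
        stress[sp.species_id] = list(tr.index[tr["stress_gene"]])

    truth = GroundTruth(
        lt50={s.species_id: s.true_lt50 for s in specs},
        slope={s.species_id: s.logit_slope for s in specs},
        strategy={s.species_id: s.strategy for s in specs},
        de=de_truth,
        shared_names=shared_truth,
        og_category=og_truth,
        stress_genes=stress,
    )
    study = StudyData(
        specs={s.species_id: s for s in specs},
        species_meta=meta,
        survival=survival,
        catalogs=catalogs,
        counts=counts,
        orthogroups=og_table,
        truth=truth,
        master_seed=seed,
    )
    if audit:
        audit_study(study)
    return study


def audit_study(study: StudyData) -> None:
    """Verify the ground truth against the emitted objects; raises on drift."""
    # shared-name truth vs catalogs (re-derived independently of the pipeline)
    def meaningful(sid: str) -> set[str]:
        return {
            a.strip().casefold()
            for a in study.catalogs[sid]
            if isinstance(a, str) and a.strip()
            and UNCHARACTERIZED not in a.casefold()
        }

    for (a, b), k in study.truth.shared_names.items():
        realized = len(meaningful(a) & meaningful(b))
        if realized != k:
            raise SimulationError(
                f"shared-name truth drifted for ({a}, {b}): {realized} != {k}"
            )

    # orthogroup categories vs emitted presence patterns
    sids = set(study.specs)
    for og, cat in study.truth.og_category.items():
        present = study.orthogroups.presence(og)
        genera = {study.species_meta[s].genus for s in present}
        subfams = {study.species_meta[s].subfamily for s in present}
        ok = {
            "I": present == frozenset(sids),
            "II": subfams == {"Myrmicinae"} and len(present) >= 2,
            "III": subfams == {"Formicinae"} and len(present) >= 2
            and len(genera) >= 2,
            "IV": len(present) >= 2 and len(genera) == 1,
            "V": len(present) == 1,
            "mixed_partial": len(subfams) == 2 and present != frozenset(sids),
        }[cat]
        if not ok:
            raise SimulationError(f"orthogroup {og} does not realize category {cat}")

    # count truth consistency: configured HS/NHS means obey the recorded log2FC
    for sid, tr in study.truth.de.items():
        ratio = tr["hs_mean"] / tr["nhs_mean"]
        expect = 2.0 ** tr["true_log2fc"]
        if not np.allclose(ratio, expect):
            raise SimulationError(f"{sid}: count means inconsistent with true log2FC")
        if study.specs[sid].strategy == "constitutive" and tr["true_de"].any():
            raise SimulationError(f"{sid}: constitutive species must have no true DE")
        cm = study.counts[sid]
        if list(cm.counts.index) != list(tr.index):
            raise SimulationError(f"{sid}: truth index mismatch with counts")
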