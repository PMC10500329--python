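"""Expression response to heat stress: TMM normalization, differential
expression, the consensus filter, HSP panels, and strategy classification.

Counts are transcript x sample integer matrices with each sample labelled
HS (heat-stressed) or NHS (control).  Normalization uses the trimmed mean
of M-values (TMM); differential transcripts are those passing the strict
consensus rule |mean log2FC| >= 2 and FDR <= 1e-3 in two independent
callers with concordant direction.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

CONDITIONS = ("HS", "NHS")

#: annotation search terms used to pull heat-shock protein transcripts,
#: matched case-insensitively as substrings
DEFAULT_HSP_TERMS: dict[str, tuple[str, ...]] = {
    "HSP70": ("Hsp70", "Hsp 70", "Heat shock protein 70"),
    "HSP90": ("Hsp90", "Hsp 90", "Heat shock protein 90"),
}


class CountMatrixError(ValueError):
    pass


@dataclass
class CountMatrix:
    """Transcript x sample counts plus the HS/NHS condition of each sample."""

    counts: pd.DataFrame  # index: transcript ids, columns: sample ids
    conditions: pd.Series  # sample id -> "HS" | "NHS"

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise CountMatrixError("duplicate transcript ids")
        if self.counts.columns.has_duplicates:
            raise CountMatrixError("duplicate sample ids")
        matrix_samples = set(self.counts.columns)
        meta_samples = set(self.conditions.index)
        if matrix_samples != meta_samples:
            diff = sorted(matrix_samples ^ meta_samples)
            raise CountMatrixError(
                f"sample mismatch between matrix and metadata: {diff}"
            )
        bad = set(self.conditions.unique()) - set(CONDITIONS)
        if bad:
            raise CountMatrixError(f"unknown conditions: {sorted(bad)}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise CountMatrixError("counts must be integers")
            self.counts = self.counts.round().astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise CountMatrixError("counts must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.conditions[s] == condition]


@dataclass
class NormalizationFactors:
    factors: pd.Series  # per-sample TMM factor, geometric mean 1
    lib_sizes: pd.Series

    @property
    def effective_lib_sizes(self) -> pd.Series:
        return self.lib_sizes * self.factors


@dataclass
class ConsensusDETSet:
    """Transcripts passing the two-caller consensus rule."""

    transcripts: list[str]
    direction: dict[str, str]  # transcript -> "up_HS" | "down_HS"
    n_up: int
    n_down: int
    n_only_one_table: int

    def __contains__(self, transcript: str) -> bool:
        return transcript in self.direction

    def __len__(self) -> int:
        return len(self.transcripts)


@dataclass
class HSPPanel:
    members: dict[str, list[str]]  # family -> matching transcript ids
    top_isoform: dict[str, str | None]  # family -> transcript with max mean value
    top_values: dict[str, pd.Series]  # family -> per-sample normalized values
    differential: dict[str, bool]  # family -> any member in the consensus set


@dataclass
class ResponseProfile:
    species_id: str
    det_count: int
    transcriptome_size: int
    det_fraction: float  # percent
    profile: str  # weak | medium | strong


@dataclass
class StrategyCall:
    species_id: str
    strategy: str  # constitutive | reactive | temperate_like | unclassified
    evidence: dict


# ---------------------------------------------------------------------------
# TMM normalization


def _quantile_fraction(col: np.ndarray, lib: float, q: float = 0.75) -> float:
    return float(np.quantile(col, q)) / lib


def tmm_factors(counts: pd.DataFrame, logratio_trim: float = 0.3,
                sum_trim: float = 0.05) -> NormalizationFactors:
    """Trimmed mean of M-values scaling factors.

    The reference sample is the one whose 75th-percentile count fraction is
    closest to the mean across samples.  For each sample, log2 count-fraction
    ratios (M) and average log2 abundances (A) are computed over transcripts
    nonzero in both the sample and the reference; the most extreme
    `logratio_trim` fraction of M and `sum_trim` fraction of A are trimmed
    from each tail, and the factor is 2 to the inverse-variance-weighted mean
    of the surviving M values.  Factors are rescaled to geometric mean 1.
    """
    if counts.shape[1] < 2:
        raise CountMatrixError("TMM needs at least two samples")
    mat = counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if (lib <= 0).any():
        bad = [s for s, l in zip(counts.columns, lib) if l <= 0]
        raise CountMatrixError(f"zero library size for sample(s) {bad}")

    f75 = np.array([_quantile_fraction(mat[:, j], lib[j]) for j in range(mat.shape[1])])
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    ref = mat[:, ref_idx]
    ref_lib = lib[ref_idx]

    factors = np.ones(mat.shape[1])
    for j in range(mat.shape[1]):
        if j == ref_idx:
            continue
        obs = mat[:, j]
        keep = (obs > 0) & (ref > 0)
        if not keep.any():
            raise CountMatrixError(
                f"sample {counts.columns[j]} shares no nonzero transcript with "
                f"the reference {counts.columns[ref_idx]}"
            )
        p_obs = obs[keep] / lib[j]
        p_ref = ref[keep] / ref_lib
        m = np.log2(p_obs / p_ref)
        a = 0.5 * np.log2(p_obs * p_ref)
        # asymptotic binomial variance of M
        w = (lib[j] - obs[keep]) / (lib[j] * obs[keep]) + (
            (ref_lib - ref[keep]) / (ref_lib * ref[keep])
        )
        if np.max(np.abs(m)) < 1e-6:
            continue
        n = m.size
        lo_m = math.floor(n * logratio_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * sum_trim) + 1
        hi_a = n + 1 - lo_a
        rank_m = stats.rankdata(m)
        rank_a = stats.rankdata(a)
        sel = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not sel.any() or w[sel].sum() == 0:
            continue
        factors[j] = 2.0 ** (np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel]))

    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(
        factors=pd.Series(factors, index=counts.columns),
        lib_sizes=pd.Series(lib, index=counts.columns),
    )


def normalize_tmm(counts: pd.DataFrame, factors: NormalizationFactors) -> pd.DataFrame:
    """Counts per million on TMM-effective library sizes."""
    missing = set(counts.columns) - set(factors.factors.index)
    if missing:
        raise CountMatrixError(f"no TMM factor for sample(s) {sorted(missing)}")
    eff = factors.effective_lib_sizes[counts.columns]
    return counts / eff * 1e6


# ---------------------------------------------------------------------------
# Differential expression


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _mom_common_dispersion(adj: np.ndarray, groups: list[np.ndarray],
                           floor: float = 1e-4) -> float:
    """Method-of-moments common NB dispersion from library-size-adjusted counts.

    For NB, var = mu + phi mu^2, so phi_g = (s2_g - mu_g)/mu_g^2.  The common
    value averages the per-gene moment estimates over well-expressed genes
    (mean > 50 adjusted counts), where the ratio estimator is nearly
    unbiased; with too few such genes it falls back to the pooled moment
    equation sum(s2 - mu) = phi * sum(mu^2) over all expressed genes.
    """
    ratios = []
    num = 0.0
    den = 0.0
    for idx in groups:
        sub = adj[:, idx]
        mu = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        well = mu > 50.0
        ratios.append((s2[well] - mu[well]) / mu[well] ** 2)
        keep = mu > 1.0
        num += float(np.sum(s2[keep] - mu[keep]))
        den += float(np.sum(mu[keep] ** 2))
    ratios = np.concatenate(ratios) if ratios else np.array([])
    if ratios.size >= 50:
        return max(float(ratios.mean()), floor)
    if den > 0:
        return max(num / den, floor)
    return floor


def _nb_logpmf(k: np.ndarray, mean: float, phi: float) -> np.ndarray:
    size = 1.0 / phi
    p = size / (size + mean)
    return stats.nbinom.logpmf(k, size, p)


def _exact_conditional_p(sa: int, sb: int, mean_a: float, mean_b: float,
                         phi_a: float, phi_b: float, enum_cap: int = 20000) -> float:
    """Two-sided exact-style p for a split of the total sa+sb between groups.

    Conditions on the total: P(S_A = a | total) is proportional to
    f_NB(a; mean_a, phi_a) * f_NB(total-a; mean_b, phi_b); the p-value sums
    the probabilities of all splits less likely than the observed one, plus
    half the probability of equally likely splits (the mid-p correction,
    which removes the conservatism of discrete exact tests).  Totals beyond
    `enum_cap` use the normal approximation of the same conditional law.
    """
    total = sa + sb
    if total == 0:
        return 1.0
    if total <= enum_cap:
        a = np.arange(total + 1)
        logp = _nb_logpmf(a, mean_a, phi_a) + _nb_logpmf(total - a, mean_b, phi_b)
        logp -= logp.max()
        prob = np.exp(logp)
        prob /= prob.sum()
        obs = prob[sa]
        lower = prob[prob < obs * (1 - 1e-12)].sum()
        ties = prob[np.abs(prob - obs) <= obs * 1e-12].sum()
        return float(min(1.0, lower + 0.5 * ties))
    # Gaussian approximation: X|X+Y=t is ~ normal with the usual conditional
    # moments of two independent normals
    va = mean_a + phi_a * mean_a**2
    vb = mean_b + phi_b * mean_b**2
    mu = mean_a + va / (va + vb) * (total - mean_a - mean_b)
    sd = math.sqrt(va * vb / (va + vb))
    z = (sa - mu) / sd
    return float(min(1.0, 2 * stats.norm.sf(abs(z))))


def _log2fc_from_cpm(cpm: pd.DataFrame, hs: list[str], nhs: list[str],
                     pseudo: float = 0.5) -> np.ndarray:
    mean_hs = cpm[hs].mean(axis=1).to_numpy()
    mean_nhs = cpm[nhs].mean(axis=1).to_numpy()
    return np.log2((mean_hs + pseudo) / (mean_nhs + pseudo))


def de_test(matrix: CountMatrix, dispersion: float | None = None,
            caller: str = "nb_exact") -> pd.DataFrame:
    """Built-in negative-binomial exact-style differential test.

    log2FC is the ratio of TMM-CPM condition means with a 0.5 pseudo-value;
    p-values come from an exact-style conditional NB test on the group count
    totals, with a common method-of-moments dispersion (floored at 1e-4);
    FDR is Benjamini-Hochberg.  Returns columns transcript_id, log2fc,
    pvalue, fdr, caller.
    """
    hs = matrix.samples_in("HS")
    nhs = matrix.samples_in("NHS")
    if len(hs) < 2 or len(nhs) < 2:
        raise CountMatrixError("need >= 2 replicates per condition")
    factors = tmm_factors(matrix.counts)
    cpm = normalize_tmm(matrix.counts, factors)
    eff = factors.effective_lib_sizes
    rel = eff / eff.mean()
    adj = (matrix.counts / rel).to_numpy(dtype=float)
    cols = list(matrix.counts.columns)
    hs_idx = np.array([cols.index(s) for s in hs])
    nhs_idx = np.array([cols.index(s) for s in nhs])

    if dispersion is None:
        dispersion = _mom_common_dispersion(adj, [hs_idx, nhs_idx])

    log2fc = _log2fc_from_cpm(cpm, hs, nhs)

    raw = matrix.counts.to_numpy()
    sa_all = raw[:, hs_idx].sum(axis=1)
    sb_all = raw[:, nhs_idx].sum(axis=1)
    na_eff = float(eff[hs].sum())
    nb_eff = float(eff[nhs].sum())
    # summing replicates divides the per-observation dispersion
    phi_a = dispersion / len(hs)
    phi_b = dispersion / len(nhs)

    pvals = np.ones(raw.shape[0])
    for i in range(raw.shape[0]):
        sa, sb = int(sa_all[i]), int(sb_all[i])
        if sa + sb == 0:
            log2fc[i] = 0.0
            continue
        lam = (sa + sb) / (na_eff + nb_eff)
        pvals[i] = _exact_conditional_p(sa, sb, lam * na_eff, lam * nb_eff, phi_a, phi_b)

    return pd.DataFrame(
        {
            "transcript_id": matrix.counts.index,
            "log2fc": log2fc,
            "pvalue": pvals,
            "fdr": bh_fdr(pvals),
            "caller": caller,
        }
    ).reset_index(drop=True)


def de_test_logcpm(matrix: CountMatrix, prior_df: float = 10.0,
                   caller: str = "modt_logcpm") -> pd.DataFrame:
    """Second lightweight caller: moderated t on log2(CPM + 0.5).

    Gene-wise pooled variances are shrunk toward the median gene variance
    with `prior_df` pseudo-degrees of freedom, which stabilizes the test at
    small replicate numbers and provides an independent line of evidence so
    the consensus filter is a genuine intersection of two analyses.
    """
    hs = matrix.samples_in("HS")
    nhs = matrix.samples_in("NHS")
    na, nb = len(hs), len(nhs)
    if na < 2 or nb < 2:
        raise CountMatrixError("need >= 2 replicates per condition")
    factors = tmm_factors(matrix.counts)
    logcpm = np.log2(normalize_tmm(matrix.counts, factors) + 0.5)
    a = logcpm[hs].to_numpy()
    b = logcpm[nhs].to_numpy()
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    df_g = na + nb - 2
    s2 = (a.var(axis=1, ddof=1) * (na - 1) + b.var(axis=1, ddof=1) * (nb - 1)) / df_g
    positive = s2[s2 > 0]
    s2_prior = float(np.median(positive)) if positive.size else 1e-8
    s2_mod = (prior_df * s2_prior + df_g * s2) / (prior_df + df_g)
    se = np.sqrt(s2_mod * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = log2fc / se
    p = 2.0 * stats.t.sf(np.abs(t), df_g + prior_df)
    p = np.where(np.isfinite(p), p, 1.0)
    zero = matrix.counts.sum(axis=1).to_numpy() == 0
    log2fc = np.where(zero, 0.0, log2fc)
    p = np.where(zero, 1.0, p)
    return pd.DataFrame(
        {
            "transcript_id": matrix.counts.index,
            "log2fc": log2fc,
            "pvalue": p,
            "fdr": bh_fdr(p),
            "caller": caller,
        }
    ).reset_index(drop=True)


def consensus_det(table_a: pd.DataFrame, table_b: pd.DataFrame,
                  fc_cut: float = 2.0, fdr_cut: float = 1e-3) -> ConsensusDETSet:
    """Intersection filter over two differential tables.

    A transcript is retained iff FDR <= fdr_cut in both tables, the two
    log2FC estimates share a sign, and the mean absolute log2FC is >= fc_cut.
    """
    a = table_a.set_index("transcript_id")
    b = table_b.set_index("transcript_id")
    common = a.index.intersection(b.index)
    n_only = len(a.index.symmetric_difference(b.index))
    if n_only:
        log.info("consensus_det: %d transcripts present in only one table", n_only)
    fa = a.loc[common]
    fb = b.loc[common]
    sig = (fa["fdr"] <= fdr_cut) & (fb["fdr"] <= fdr_cut)
    same_sign = np.sign(fa["log2fc"]) == np.sign(fb["log2fc"])
    nonzero = (fa["log2fc"] != 0) & (fb["log2fc"] != 0)
    mean_abs = (fa["log2fc"].abs() + fb["log2fc"].abs()) / 2.0
    keep = sig & same_sign & nonzero & (mean_abs >= fc_cut)
    chosen = common[keep.to_numpy()]
    direction = {
        t: ("up_HS" if fa.loc[t, "log2fc"] > 0 else "down_HS") for t in chosen
    }
    n_up = sum(1 for d in direction.values() if d == "up_HS")
    return ConsensusDETSet(
        transcripts=list(chosen),
        direction=direction,
        n_up=n_up,
        n_down=len(direction) - n_up,
        n_only_one_table=n_only,
    )


# ---------------------------------------------------------------------------
# HSP panels, profiles, strategies


def find_hsp_transcripts(
    annotations: pd.Series,
    normalized: pd.DataFrame,
    terms: dict[str, tuple[str, ...]] | None = None,
    det: ConsensusDETSet | None = None,
) -> HSPPanel:
    """Pull heat-shock protein transcripts by annotation substring match.

    Per family the top isoform is the matching transcript with the highest
    mean normalized value across all samples; the differential flag records
    whether any family member is in the consensus DET set.
    """
    terms = terms or DEFAULT_HSP_TERMS
    members: dict[str, list[str]] = {fam: [] for fam in terms}
    for tid, ann in annotations.items():
        if not isinstance(ann, str):
            continue
        low = ann.lower()
        for fam, fam_terms in terms.items():
            if any(term.lower() in low for term in fam_terms):
                members[fam].append(tid)
    if not any(members.values()):
        warnings.warn("no transcript matched any HSP search term", stacklevel=2)
    top: dict[str, str | None] = {}
    values: dict[str, pd.Series] = {}
    flags: dict[str, bool] = {}
    for fam, tids in members.items():
        present = [t for t in tids if t in normalized.index]
        if present:
            mean_expr = normalized.loc[present].mean(axis=1)
            top[fam] = str(mean_expr.idxmax())
            values[fam] = normalized.loc[top[fam]]
        else:
            top[fam] = None
            values[fam] = pd.Series(dtype=float)
        flags[fam] = bool(det and any(t in det for t in tids))
    return HSPPanel(members=members, top_isoform=top, top_values=values,
                    differential=flags)


def classify_profile(det_count: int, transcriptome_size: int, species_id: str = "",
                     cuts: tuple[float, float] = (0.3, 5.0)) -> ResponseProfile:
    """Group a species' response by its DET percentage of the transcriptome:
    weak (< cuts[0] %), medium, or strong (> cuts[1] %)."""
    if transcriptome_size <= 0:
        raise ValueError("transcriptome size must be positive")
    frac = 100.0 * det_count / transcriptome_size
    if frac < cuts[0]:
        profile = "weak"
    elif frac > cuts[1]:
        profile = "strong"
    else:
        profile = "medium"
    return ResponseProfile(
        species_id=species_id,
        det_count=det_count,
        transcriptome_size=transcriptome_size,
        det_fraction=frac,
        profile=profile,
    )


def call_strategy(
    profile: ResponseProfile,
    habitat: str,
    hsp_differential: dict[str, bool],
    decline_width: float | None,
) -> StrategyCall:
    """Classify a species' heat-stress strategy.

    Desert species with a weak response and no HSP70/90 induction keep their
    chaperones constitutively high; desert species with a medium/strong
    response and induced HSPs are reactive; temperate species are labelled
    temperate_like regardless of response size.
    """
    any_hsp = any(hsp_differential.values())
    evidence = {
        "profile": profile.profile,
        "habitat": habitat,
        "hsp_differential": dict(hsp_differential),
        "decline_width": decline_width,
    }
    if habitat == "temperate":
        strategy = "temperate_like"
    elif habitat == "desert" and profile.profile == "weak" and not any_hsp:
        strategy = "constitutive"
    elif habitat == "desert" and profile.profile in ("medium", "strong") and any_hsp:
        strategy = "reactive"
    else:
        strategy = "unclassified"
    return StrategyCall(species_id=profile.species_id, strategy=strategy,
                        evidence=evidence)
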