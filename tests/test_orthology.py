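"""Orthogroup categories, restricted-gene status, enrichment, and summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

from antheat import orthology, simulate
from antheat.orthology import OrthogroupIntegrityError, OrthogroupTable

META = {m.species_id: m for m in simulate.DEFAULT_SPECIES_META}
ALL = list(META)


def _table(patterns):
    """patterns: dict og -> list of (species, [genes])."""
    return OrthogroupTable(
        members={og: dict(cells) for og, cells in patterns.items()},
        species=ALL,
    )


class TestClassify:
    def test_definition_cases(self):
        table = _table(
            {
                "og_all": [(s, [f"{s}_g1"]) for s in ALL],
                "og_cata": [("Cbom", ["c1"]), ("Chol", ["c2"])],
                "og_myrm": [("Orob", ["o1"]), ("Msab", ["m1"])],
                "og_form": [("Cbom", ["c3"]), ("Mbag", ["b1"]), ("Ffus", ["f1"])],
                "og_single": [("Msab", ["m2"])],
                "og_mixed": [("Cbom", ["c4"]), ("Msab", ["m3"])],
            }
        )
        cats = orthology.classify_orthogroups(table, META)
        assert cats == {
            "og_all": "I",
            "og_cata": "IV",  # same-genus precedence over Formicinae-only
            "og_myrm": "II",
            "og_form": "III",
            "og_single": "V",
            "og_mixed": "mixed_partial",
        }

    def test_empty_orthogroup_raises(self):
        table = _table({"og": [("Cbom", [])]})
        with pytest.raises(OrthogroupIntegrityError):
            orthology.classify_orthogroups(table, META)

    def test_recovers_generator_truth_exactly(self):
        """200 simulated orthogroups with a 50/50 I-vs-V mixture: the
        classifier recovers every generated label."""
        spec_names = {m.species_id: m for m in simulate.DEFAULT_SPECIES_META}
        catalogs = {
            sid: pd.Series(
                [f"protein {i}" for i in range(400)],
                index=[f"{sid}_t{i}" for i in range(400)],
            )
            for sid in spec_names
        }
        table, truth = simulate.simulate_orthogroups(
            catalogs, spec_names, {"I": 0.5, "V": 0.5}, n_orthogroups=200, seed=3
        )
        cats = orthology.classify_orthogroups(table, spec_names)
        assert cats == truth

    def test_full_mixture_recovery(self, study):
        cats = orthology.classify_orthogroups(study.orthogroups, study.species_meta)
        assert cats == study.truth.og_category


class TestGeneStatus:
    def test_status_mapping_and_partition(self, study):
        cats = orthology.classify_orthogroups(study.orthogroups, study.species_meta)
        for sid in ALL:
            status = orthology.gene_status(
                cats, study.orthogroups, sid, catalog=study.catalogs[sid].index
            )
            # partition: every catalog gene is exactly one of the three states
            counts = pd.Series(list(status.values())).value_counts()
            assert counts.sum() == len(study.catalogs[sid])
            assert set(counts.index) <= {"conserved", "restricted", "unassigned"}

    def test_category_contradiction_detected(self):
        table = _table({"og": [("Ffus", ["f1"]), ("Msab", ["m1"])]})
        # forged assignment: Formicinae member inside a Myrmicinae-only group
        with pytest.raises(OrthogroupIntegrityError):
            orthology.check_category_consistency({"og": "II"}, table, META)

    def test_restricted_iff_lineage_specific(self):
        table = _table(
            {
                "og1": [(s, [f"{s}_a"]) for s in ALL],
                "og2": [("Mbag", ["Mbag_b"])],
            }
        )
        cats = orthology.classify_orthogroups(table, META)
        status = orthology.gene_status(cats, table, "Mbag")
        assert status["Mbag_a"] == "conserved"
        assert status["Mbag_b"] == "restricted"


def _fisher_enumeration(table):
    """Independent oracle: two-sided Fisher p by enumerating every 2x2 table
    with the same margins and summing hypergeometric point probabilities
    no larger than the observed one."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def point(x):
        return comb(r1, x, exact=True) * comb(r2, c1 - x, exact=True)

    total = comb(n, c1, exact=True)
    p_obs = point(a)
    acc = 0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = point(x)
        if px <= p_obs:
            acc += px
    return acc / total


class TestEnrichment:
    def test_no_association(self):
        status = {}
        for i in range(10):
            status[f"d_r{i}"] = "restricted"
        for i in range(90):
            status[f"d_c{i}"] = "conserved"
        for i in range(100):
            status[f"n_r{i}"] = "restricted"
        for i in range(900):
            status[f"n_c{i}"] = "conserved"
        det = [g for g in status if g.startswith("d_")]
        res = orthology.restricted_enrichment(status, det, "sp")
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "table",
        [
            [[3, 7], [10, 80]],
            [[0, 10], [5, 85]],
            [[12, 2], [30, 55]],
            [[1, 1], [1, 1]],
        ],
    )
    def test_p_matches_full_enumeration(self, table):
        status = {}
        det = []
        (a, b), (c, d) = table
        for i in range(a):
            status[f"dr{i}"] = "restricted"; det.append(f"dr{i}")
        for i in range(b):
            status[f"dc{i}"] = "conserved"; det.append(f"dc{i}")
        for i in range(c):
            status[f"nr{i}"] = "restricted"
        for i in range(d):
            status[f"nc{i}"] = "conserved"
        res = orthology.restricted_enrichment(status, det, "sp")
        assert res.p == pytest.approx(_fisher_enumeration(table), abs=1e-12)

    def test_symmetry_under_row_and_column_swap(self):
        p1 = stats.fisher_exact([[3, 7], [10, 80]]).pvalue
        p2 = stats.fisher_exact([[80, 10], [7, 3]]).pvalue
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_empty_det_is_degenerate(self):
        status = {"g1": "restricted", "g2": "conserved"}
        res = orthology.restricted_enrichment(status, [], "sp")
        assert res.degenerate and res.p == 1.0

    def test_power_against_twofold_enrichment(self):
        """DET over-sampled 2x from restricted genes are flagged as an
        increase with p < .01 in nearly all replicates."""
        rng = np.random.default_rng(17)
        genes = [f"g{i}" for i in range(5000)]
        restricted = set(genes[:1000])  # 20% restricted
        status = {g: ("restricted" if g in restricted else "conserved")
                  for g in genes}
        weights = np.where([g in restricted for g in genes], 2.0, 1.0)
        weights /= weights.sum()
        hits = 0
        for _ in range(100):
            det = rng.choice(genes, size=500, replace=False, p=weights)
            res = orthology.restricted_enrichment(status, det, "sp")
            hits += (res.direction == "increase") and (res.p < 0.01)
        assert hits >= 95


class TestSummary:
    def test_single_species_all_assigned(self):
        table = OrthogroupTable(
            members={"og1": {"sp": ["g1", "g2", "g3"]}}, species=["sp"]
        )
        s = orthology.summarize_orthology(table, {"sp": ["g1", "g2", "g3"]})
        assert s.pct_assigned == 100.0
        assert s.pct_species_specific_orthogroups == 100.0
        assert s.per_species.loc["sp", "pct_genes_in_species_specific"] == 100.0

    def test_counts_invariant_to_orthogroup_order(self, study):
        cats = orthology.classify_orthogroups(study.orthogroups, study.species_meta)
        catalogs = {s: study.catalogs[s].index for s in ALL}
        s1 = orthology.summarize_orthology(study.orthogroups, catalogs, cats)
        shuffled = OrthogroupTable(
            members=dict(reversed(list(study.orthogroups.members.items()))),
            species=ALL,
        )
        s2 = orthology.summarize_orthology(shuffled, catalogs, cats)
        pd.testing.assert_frame_equal(s1.per_species, s2.per_species)

    def test_category_proportions_match_generator_mixture(self, study):
        """The realized category counts reproduce the requested mixture
        exactly (largest-remainder rounding of the proportions)."""
        cats = orthology.classify_orthogroups(study.orthogroups, study.species_meta)
        realized = pd.Series(cats).value_counts().to_dict()
        n = len(study.orthogroups)
        mixture = dict(simulate.DEFAULT_CATEGORY_MIXTURE)
        mixture["mixed_partial"] = mixture.pop("mixed")
        expected = simulate._mixture_counts(mixture, n)
        assert realized == {k: v for k, v in expected.items() if v}
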