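"""Orthogroup taxonomic categories and taxonomically restricted genes.

Orthogroups (from an OrthoFinder-style table) are classified by their
species-presence pattern into five categories: I - present in all study
species; II - only Myrmicinae; III - only Formicinae; IV - only the two
congeneric (Cataglyphis) species; V - species-specific.  Orthogroups that
span both subfamilies without covering every species fall outside the five
categories and are labelled mixed_partial (treated as conserved).  Genes in
categories IV/V are taxonomically restricted; I/II/III/mixed_partial genes
are conserved.  A Fisher exact test asks whether restricted genes are over-
or under-represented among differentially expressed transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CATEGORIES = ("I", "II", "III", "IV", "V", "mixed_partial")
RESTRICTED_CATEGORIES = frozenset({"IV", "V"})


class OrthogroupIntegrityError(ValueError):
    pass


@dataclass(frozen=True)
class SpeciesMeta:
    species_id: str
    subfamily: str  # Formicinae | Myrmicinae
    genus: str
    habitat: str  # desert | temperate

    def __post_init__(self) -> None:
        if self.subfamily not in ("Formicinae", "Myrmicinae"):
            raise ValueError(f"unknown subfamily {self.subfamily!r}")
        if self.habitat not in ("desert", "temperate"):
            raise ValueError(f"unknown habitat {self.habitat!r}")


@dataclass
class OrthogroupTable:
    """orthogroup id -> species id -> gene id list."""

    members: dict[str, dict[str, list[str]]]
    species: list[str]

    def __post_init__(self) -> None:
        seen: dict[str, dict[str, str]] = {sp: {} for sp in self.species}
        for og, per_species in self.members.items():
            unknown = set(per_species) - set(self.species)
            if unknown:
                raise OrthogroupIntegrityError(
                    f"orthogroup {og} references unknown species {sorted(unknown)}"
                )
            for sp in self.species:  # canonical form: every species listed
                per_species.setdefault(sp, [])
            for sp, genes in per_species.items():
                for g in genes:
                    if g in seen[sp]:
                        raise OrthogroupIntegrityError(
                            f"gene {g} of {sp} appears in both {seen[sp][g]} and {og}"
                        )
                    seen[sp][g] = og

    def presence(self, og: str) -> frozenset[str]:
        return frozenset(
            sp for sp, genes in self.members[og].items() if len(genes) > 0
        )

    def genes_of(self, species: str):
        for og, per_species in self.members.items():
            for g in per_species.get(species, ()):
                yield og, g

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class EnrichmentResult:
    species_id: str
    table: np.ndarray  # [[det_restricted, det_conserved], [rest_restricted, rest_conserved]]
    odds_ratio: float
    p: float
    direction: str  # increase | decrease | none
    haldane_corrected: bool = False
    degenerate: bool = False


@dataclass
class OrthoSummary:
    per_species: pd.DataFrame
    total_genes: int
    total_assigned: int
    pct_assigned: float
    n_orthogroups: int
    n_species_specific: int
    pct_species_specific_orthogroups: float
    genes_in_species_specific: int
    pct_genes_in_species_specific: float

    @classmethod
    def from_counts(
        cls,
        genes_total: dict[str, int],
        genes_in_orthogroups: dict[str, int],
        species_specific_orthogroups: dict[str, int],
        genes_in_species_specific: dict[str, int],
        n_orthogroups: int,
        orthogroups_containing: dict[str, int] | None = None,
        species_specific_total: int | None = None,
    ) -> "OrthoSummary":
        """Build the summary from count-level inputs (the arithmetic layer).

        `species_specific_total` overrides the study-wide species-specific
        orthogroup count when the per-species breakdown is known to be
        incomplete (orthology tools may report the study-wide total from a
        slightly different accounting than the per-species rows).
        """
        rows = {}
        for sp in genes_total:
            total = genes_total[sp]
            assigned = genes_in_orthogroups[sp]
            if assigned > total:
                raise ValueError(f"{sp}: assigned genes exceed gene total")
            row = {
                "genes_total": total,
                "genes_in_orthogroups": assigned,
                "unassigned": total - assigned,
                "pct_in_orthogroups": 100.0 * assigned / total,
                "pct_unassigned": 100.0 * (total - assigned) / total,
                "species_specific_orthogroups": species_specific_orthogroups[sp],
                "genes_in_species_specific": genes_in_species_specific[sp],
                "pct_genes_in_species_specific": (
                    100.0 * genes_in_species_specific[sp] / total
                ),
            }
            if orthogroups_containing is not None:
                row["orthogroups_containing"] = orthogroups_containing[sp]
                row["pct_orthogroups_containing"] = (
                    100.0 * orthogroups_containing[sp] / n_orthogroups
                )
            rows[sp] = row
        per_species = pd.DataFrame(rows).T
        total = sum(genes_total.values())
        assigned = sum(genes_in_orthogroups.values())
        n_ss = (
            species_specific_total
            if species_specific_total is not None
            else sum(species_specific_orthogroups.values())
        )
        g_ss = sum(genes_in_species_specific.values())
        return cls(
            per_species=per_species,
            total_genes=total,
            total_assigned=assigned,
            pct_assigned=100.0 * assigned / total,
            n_orthogroups=n_orthogroups,
            n_species_specific=n_ss,
            pct_species_specific_orthogroups=100.0 * n_ss / n_orthogroups,
            genes_in_species_specific=g_ss,
            pct_genes_in_species_specific=100.0 * g_ss / total,
        )


def classify_orthogroups(
    table: OrthogroupTable, species_meta: dict[str, SpeciesMeta]
) -> dict[str, str]:
    """Assign each orthogroup its taxonomic category from species presence.

    Precedence: V (single species) -> IV (>= 2 species, all one genus) ->
    II/III (>= 2 species, all one subfamily) -> I (all study species) ->
    mixed_partial (spans both subfamilies without covering all species).
    """
    missing = set(table.species) - set(species_meta)
    if missing:
        raise KeyError(f"species without metadata: {sorted(missing)}")
    all_species = frozenset(table.species)
    out: dict[str, str] = {}
    for og in table.members:
        present = table.presence(og)
        if not present:
            raise OrthogroupIntegrityError(f"orthogroup {og} is empty in every species")
        if len(present) == 1:
            out[og] = "V"
            continue
        genera = {species_meta[sp].genus for sp in present}
        if len(genera) == 1:
            out[og] = "IV"
            continue
        subfamilies = {species_meta[sp].subfamily for sp in present}
        if subfamilies == {"Myrmicinae"}:
            out[og] = "II"
        elif subfamilies == {"Formicinae"}:
            out[og] = "III"
        elif present == all_species:
            out[og] = "I"
        else:
            out[og] = "mixed_partial"
    return out


def gene_status(
    assignments: dict[str, str],
    table: OrthogroupTable,
    species: str,
    catalog=None,
) -> dict[str, str]:
    """Map each gene of one species to conserved / restricted / unassigned.

    Restricted genes sit in category IV or V orthogroups; genes in I/II/III
    (or cross-subfamily mixed_partial) orthogroups are conserved.  Genes of
    `catalog` absent from every orthogroup are labelled unassigned.
    """
    meta_subfamily: dict[str, str] = {}
    status: dict[str, str] = {}
    for og, gene in table.genes_of(species):
        cat = assignments[og]
        status[gene] = "restricted" if cat in RESTRICTED_CATEGORIES else "conserved"
    if catalog is not None:
        for gene in catalog:
            if gene not in status:
                status[gene] = "unassigned"
    return status


def check_category_consistency(
    assignments: dict[str, str],
    table: OrthogroupTable,
    species_meta: dict[str, SpeciesMeta],
) -> None:
    """Integrity check: a subfamily-restricted category may only contain
    species of that subfamily (e.g. no Formicinae gene in a category-II
    orthogroup)."""
    wanted = {"II": "Myrmicinae", "III": "Formicinae"}
    for og, cat in assignments.items():
        if cat not in wanted:
            continue
        for sp in table.presence(og):
            if species_meta[sp].subfamily != wanted[cat]:
                raise OrthogroupIntegrityError(
                    f"orthogroup {og} is category {cat} but contains {sp} "
                    f"({species_meta[sp].subfamily})"
                )


def restricted_enrichment(
    status: dict[str, str],
    det_genes,
    species: str,
    include_unassigned: bool = False,
) -> EnrichmentResult:
    """Fisher exact test of restricted-gene share among DET vs the rest.

    Builds the 2x2 table {DET, non-DET} x {restricted, conserved} over
    assigned genes (optionally counting unassigned genes as restricted) and
    evaluates the two-sided exact p by point-probability summation.
    """
    det = set(det_genes)
    unknown = det - set(status)
    if unknown:
        import warnings

        warnings.warn(
            f"{len(unknown)} DET gene(s) absent from the status map", stacklevel=2
        )
        det -= unknown

    def is_restricted(s: str) -> bool | None:
        if s == "restricted":
            return True
        if s == "conserved":
            return False
        return True if include_unassigned else None

    a = b = c = d = 0
    for gene, s in status.items():
        r = is_restricted(s)
        if r is None:
            continue
        if gene in det:
            a += r
            b += not r
        else:
            c += r
            d += not r
    table = np.array([[a, b], [c, d]], dtype=np.int64)
    if a + b == 0:
        return EnrichmentResult(species, table, float("nan"), 1.0, "none",
                                degenerate=True)
    res = stats.fisher_exact(table, alternative="two-sided")
    haldane = False
    if 0 in (a, b, c, d):
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        haldane = True
    else:
        odds = (a * d) / (b * c)
    det_frac = a / (a + b)
    rest_frac = c / (c + d) if (c + d) else float("nan")
    if det_frac > rest_frac:
        direction = "increase"
    elif det_frac < rest_frac:
        direction = "decrease"
    else:
        direction = "none"
    return EnrichmentResult(
        species_id=species,
        table=table,
        odds_ratio=float(odds),
        p=float(res.pvalue),
        direction=direction,
        haldane_corrected=haldane,
    )


def summarize_orthology(
    table: OrthogroupTable,
    catalogs: dict[str, "pd.Index | list[str]"],
    assignments: dict[str, str] | None = None,
) -> OrthoSummary:
    """Per-species and study-wide orthology summary counts and percentages."""
    if assignments is None:
        # species-specific detection needs no clade map
        assignments = {
            og: ("V" if len(table.presence(og)) == 1 else "other")
            for og in table.members
        }
    genes_total = {sp: len(catalogs[sp]) for sp in table.species}
    genes_in: dict[str, int] = {sp: 0 for sp in table.species}
    ss_ogs: dict[str, int] = {sp: 0 for sp in table.species}
    genes_ss: dict[str, int] = {sp: 0 for sp in table.species}
    containing: dict[str, int] = {sp: 0 for sp in table.species}
    for og, per_species in table.members.items():
        present = table.presence(og)
        for sp in present:
            containing[sp] += 1
            genes_in[sp] += len(per_species[sp])
        if assignments.get(og) == "V":
            (sp,) = present
            ss_ogs[sp] += 1
            genes_ss[sp] += len(per_species[sp])
    for sp in table.species:
        if genes_in[sp] > genes_total[sp]:
            raise OrthogroupIntegrityError(
                f"{sp}: more genes in orthogroups ({genes_in[sp]}) than in the "
                f"catalog ({genes_total[sp]})"
            )
    return OrthoSummary.from_counts(
        genes_total=genes_total,
        genes_in_orthogroups=genes_in,
        species_specific_orthogroups=ss_ogs,
        genes_in_species_specific=genes_ss,
        n_orthogroups=len(table),
        orthogroups_containing=containing,
    )
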