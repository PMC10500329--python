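"""Tabular I/O for the pipeline.

Dialects: comma-separated survival tables; tab-separated count matrices,
sample/annotation/species metadata, differential tables, and OrthoFinder-
style orthogroup tables (cells are comma-separated gene id lists).  All
files UTF-8 with '.' decimal separator.  Counts are strictly integer at
ingest; normalized values are produced, never read back.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .expression import CountMatrix
from .orthology import OrthogroupTable, SpeciesMeta
from .thermal import SurvivalObservation

log = logging.getLogger(__name__)

SURVIVAL_COLUMNS = ["species", "temperature_c", "tube_id", "n_total", "n_dead"]


class TableFormatError(ValueError):
    pass


@dataclass
class StudyConfig:
    """Paths and thresholds for one study run; the seed is echoed in reports."""

    survival_path: str = "survival.csv"
    counts_paths: dict = field(default_factory=dict)  # species -> counts TSV
    samples_paths: dict = field(default_factory=dict)  # species -> metadata TSV
    annotation_paths: dict = field(default_factory=dict)
    orthogroups_path: str = "orthogroups.tsv"
    species_meta_path: str = "species_meta.tsv"
    fc_cut: float = 2.0
    fdr_cut: float = 1e-3
    overlap_alpha: float = 0.01
    mc_iterations: int = 10000
    utl_alpha: float = 0.05
    survival_upper: float = 0.90
    survival_lower: float = 0.05
    profile_cuts: tuple = (0.3, 5.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fc_cut", "fdr_cut", "overlap_alpha", "utl_alpha",
                     "survival_upper", "survival_lower"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mc_iterations < 1:
            raise ValueError("mc_iterations must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if "profile_cuts" in data:
            data["profile_cuts"] = tuple(data["profile_cuts"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["profile_cuts"] = list(self.profile_cuts)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# readers


def read_survival_table(path) -> list[SurvivalObservation]:
    """Read the tube-level survival CSV (species,temperature_c,tube_id,n_total,n_dead)."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in SURVIVAL_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"survival table missing column(s): {missing}")
    out = []
    for i, row in df.iterrows():
        try:
            n_total = int(row["n_total"])
            n_dead = int(row["n_dead"])
        except (TypeError, ValueError) as exc:
            raise TableFormatError(
                f"survival table row {i + 2}: non-integer count"
            ) from exc
        try:
            temperature = float(row["temperature_c"])
        except (TypeError, ValueError) as exc:
            raise TableFormatError(
                f"survival table row {i + 2}: unparseable temperature "
                f"{row['temperature_c']!r}"
            ) from exc
        out.append(
            SurvivalObservation(
                species_id=row["species"],
                temperature=temperature,
                tube_id=row["tube_id"],
                n_total=n_total,
                n_dead=n_dead,
            )
        )
    return out


def read_counts(path, meta_path) -> CountMatrix:
    """Read a transcript x sample counts TSV plus its sample metadata TSV."""
    df = pd.read_csv(path, sep="\t")
    if "transcript_id" not in df.columns:
        raise TableFormatError("counts table missing column: transcript_id")
    df = df.set_index("transcript_id")
    df.index.name = None
    meta = pd.read_csv(meta_path, sep="\t")
    for col in ("sample", "condition"):
        if col not in meta.columns:
            raise TableFormatError(f"sample metadata missing column: {col}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise TableFormatError(f"non-numeric count in sample column {col}")
        if (vals < 0).any():
            raise TableFormatError(f"negative count in sample column {col}")
        if not np.allclose(vals, vals.round()):
            raise TableFormatError(f"non-integer count in sample column {col}")
        df[col] = vals.astype(np.int64)
    conditions = pd.Series(meta["condition"].values, index=meta["sample"].values)
    return CountMatrix(counts=df, conditions=conditions)


def read_annotations(path) -> pd.Series:
    """transcript_id -> annotation string (may be empty)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("transcript_id", "annotation"):
        if col not in df.columns:
            raise TableFormatError(f"annotation table missing column: {col}")
    if df["transcript_id"].duplicated().any():
        dup = df["transcript_id"][df["transcript_id"].duplicated()].iloc[0]
        raise TableFormatError(f"duplicate transcript id in annotations: {dup}")
    return pd.Series(
        df["annotation"].values, index=df["transcript_id"].values, name="annotation"
    )


def read_species_meta(path) -> dict[str, SpeciesMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = ["species", "subfamily", "genus", "habitat"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise TableFormatError(f"species metadata missing column(s): {missing}")
    if df["species"].duplicated().any():
        raise TableFormatError("duplicate species id in species metadata")
    return {
        r["species"]: SpeciesMeta(r["species"], r["subfamily"], r["genus"], r["habitat"])
        for _, r in df.iterrows()
    }


def read_orthogroups(path, species_list) -> OrthogroupTable:
    """Read an OrthoFinder-dialect Orthogroups.tsv.

    First column is the orthogroup id; one column per species; cells are
    comma-separated gene id lists, possibly empty.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty and len(df.columns) == 0:
        log.warning("orthogroup table %s is empty", path)
        return OrthogroupTable(members={}, species=list(species_list))
    og_col = df.columns[0]
    unknown = set(df.columns[1:]) - set(species_list)
    if unknown:
        raise TableFormatError(f"unknown species column(s): {sorted(unknown)}")
    members: dict[str, dict[str, list[str]]] = {}
    for _, row in df.iterrows():
        og = row[og_col]
        members[og] = {}
        for sp in df.columns[1:]:
            cell = row[sp].strip()
            members[og][sp] = (
                [g.strip() for g in cell.split(",") if g.strip()] if cell else []
            )
    if not members:
        log.warning("orthogroup table %s has no rows", path)
    return OrthogroupTable(members=members, species=list(species_list))


def read_differential_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    needed = ["transcript_id", "log2fc", "pvalue", "fdr", "caller"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise TableFormatError(f"differential table missing column(s): {missing}")
    return df


# ---------------------------------------------------------------------------
# writers (inverse of each reader; round-trips exactly)


def write_survival_table(observations, path) -> None:
    rows = [
        {
            "species": o.species_id,
            "temperature_c": o.temperature,
            "tube_id": o.tube_id,
            "n_total": o.n_total,
            "n_dead": o.n_dead,
        }
        for o in observations
    ]
    pd.DataFrame(rows, columns=SURVIVAL_COLUMNS).to_csv(path, index=False)


def write_counts(matrix: CountMatrix, path, meta_path) -> None:
    matrix.counts.rename_axis("transcript_id").to_csv(path, sep="\t")
    meta = pd.DataFrame(
        {
            "sample": list(matrix.counts.columns),
            "condition": [matrix.conditions[s] for s in matrix.counts.columns],
            "replicate": [
                sum(
                    1
                    for t in matrix.counts.columns[: i + 1]
                    if matrix.conditions[t] == matrix.conditions[s]
                )
                for i, s in enumerate(matrix.counts.columns)
            ],
        }
    )
    meta.to_csv(meta_path, sep="\t", index=False)


def write_annotations(catalog: pd.Series, path) -> None:
    pd.DataFrame(
        {"transcript_id": catalog.index, "annotation": catalog.values}
    ).to_csv(path, sep="\t", index=False)


def write_species_meta(meta: dict[str, SpeciesMeta], path) -> None:
    pd.DataFrame(
        [
            {
                "species": m.species_id,
                "subfamily": m.subfamily,
                "genus": m.genus,
                "habitat": m.habitat,
            }
            for m in meta.values()
        ]
    ).to_csv(path, sep="\t", index=False)


def write_orthogroups(table: OrthogroupTable, path) -> None:
    rows = []
    for og in table.members:
        row = {"Orthogroup": og}
        for sp in table.species:
            row[sp] = ", ".join(table.members[og].get(sp, []))
        rows.append(row)
    pd.DataFrame(rows, columns=["Orthogroup", *table.species]).to_csv(
        path, sep="\t", index=False
    )


def write_differential_table(df: pd.DataFrame, path) -> None:
    df[["transcript_id", "log2fc", "pvalue", "fdr", "caller"]].to_csv(
        path, sep="\t", index=False
    )


def write_study(study, outdir) -> dict[str, Path]:
    """Emit a simulated study in exactly the formats the readers consume,
    plus a ground-truth JSON for tests."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["survival"] = outdir / "survival.csv"
    write_survival_table(study.survival, paths["survival"])
    for sid, cm in study.counts.items():
        paths[f"counts_{sid}"] = outdir / f"{sid}_counts.tsv"
        paths[f"samples_{sid}"] = outdir / f"{sid}_samples.tsv"
        write_counts(cm, paths[f"counts_{sid}"], paths[f"samples_{sid}"])
    for sid, cat in study.catalogs.items():
        paths[f"annotations_{sid}"] = outdir / f"{sid}_annotations.tsv"
        write_annotations(cat, paths[f"annotations_{sid}"])
    paths["orthogroups"] = outdir / "orthogroups.tsv"
    write_orthogroups(study.orthogroups, paths["orthogroups"])
    paths["species_meta"] = outdir / "species_meta.tsv"
    write_species_meta(study.species_meta, paths["species_meta"])
    truth = {
        "master_seed": study.master_seed,
        "lt50": study.truth.lt50,
        "slope": study.truth.slope,
        "strategy": study.truth.strategy,
        "shared_names": {f"{a}|{b}": k for (a, b), k in study.truth.shared_names.items()},
        "og_category": study.truth.og_category,
        "stress_genes": study.truth.stress_genes,
        "true_de": {
            sid: sorted(tr.index[tr["true_de"]]) for sid, tr in study.truth.de.items()
        },
    }
    paths["ground_truth"] = outdir / "ground_truth.json"
    with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return paths


def load_study_dir(study_dir):
    """Reassemble a StudyData from a directory written by :func:`write_study`.

    The ground-truth record is left empty except for the master seed; loaded
    studies carry only what the files contain.
    """
    from .simulate import GroundTruth, StudyData

    d = Path(study_dir)
    meta = read_species_meta(d / "species_meta.tsv")
    survival = read_survival_table(d / "survival.csv")
    catalogs = {sid: read_annotations(d / f"{sid}_annotations.tsv") for sid in meta}
    counts = {
        sid: read_counts(d / f"{sid}_counts.tsv", d / f"{sid}_samples.tsv")
        for sid in meta
        if (d / f"{sid}_counts.tsv").exists()
    }
    og_table = read_orthogroups(d / "orthogroups.tsv", list(meta))
    seed = 0
    truth_file = d / "ground_truth.json"
    if truth_file.exists():
        seed = json.loads(truth_file.read_text()).get("master_seed", 0)
    return StudyData(
        specs={},
        species_meta=meta,
        survival=survival,
        catalogs=catalogs,
        counts=counts,
        orthogroups=og_table,
        truth=GroundTruth({}, {}, {}, {}, {}, {}, {}),
        master_seed=seed,
    )


# ---------------------------------------------------------------------------
# reports


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="index"))
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_report(results: dict, outdir) -> dict[str, Path]:
    """Write the machine-readable report plus TSV summary tables.

    `results` is the nested mapping produced by the pipeline; the report
    echoes seed and config.  Outputs are deterministic (sorted keys, no
    timestamps), so identical inputs produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["report"] = outdir / "report.json"
    with open(paths["report"], "w", encoding="utf-8") as fh:
        json.dump(_jsonable(results), fh, indent=1, sort_keys=True)
        fh.write("\n")

    overlaps = results.get("overlap", {})
    if overlaps is not None:
        rows = [
            {
                "species_a": o["species_a"] if isinstance(o, dict) else o.species_a,
                "species_b": o["species_b"] if isinstance(o, dict) else o.species_b,
                "observed": o["observed"] if isinstance(o, dict) else o.observed,
                "null_mean": o["null_mean"] if isinstance(o, dict) else o.null_mean,
                "null_sd": o["null_sd"] if isinstance(o, dict) else o.null_sd,
                "p": o["p"] if isinstance(o, dict) else o.p,
                "significant": (
                    o["p"] < o.get("alpha", 0.01)
                    if isinstance(o, dict)
                    else o.significant
                ),
            }
            for o in (overlaps.values() if isinstance(overlaps, dict) else overlaps)
        ]
        paths["overlap_table"] = outdir / "overlap_pairs.tsv"
        pd.DataFrame(
            rows,
            columns=[
                "species_a", "species_b", "observed", "null_mean", "null_sd",
                "p", "significant",
            ],
        ).to_csv(paths["overlap_table"], sep="\t", index=False)

    summary = results.get("orthology_summary")
    if summary is not None:
        paths["orthology_table"] = outdir / "orthology_summary.tsv"
        per_species = (
            summary.per_species
            if hasattr(summary, "per_species")
            else pd.DataFrame(summary["per_species"]).T
        )
        per_species.rename_axis("species").to_csv(paths["orthology_table"], sep="\t")
    return paths
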