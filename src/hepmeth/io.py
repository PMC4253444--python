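"""Shared domain types, file formats, and coordinate conventions.

The pipeline operates on three tabular objects, all held as pandas
DataFrames with a fixed schema:

* **beta matrix** — probes x samples grid of methylation fractions
  (beta values) in [0, 1]; missing values allowed.
* **probe manifest** — per-probe genomic annotation: chromosome, 1-based
  position, strand, associated gene, genic feature (TSS1500 .. 3UTR or
  Intergenic) and CpG-island relation (Island / shores / shelves /
  OpenSea).  The manifest's canonical (chromosome, position) sort order
  defines what "consecutive probes" means downstream.
* **sample sheet** — per-sample tissue class, disease etiology, TNM
  stage (tumors only) and clinical covariates.

Coordinates: manifest positions are 1-based (array annotation
convention); everything exported as bedGraph/BED is 0-based half-open
(UCSC convention).
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GENIC_FEATURES = ("TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR", "Intergenic")
ISLAND_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")
TISSUE_CLASSES = (
    "normal",
    "cirrhosis",
    "HCC",
    "hepatocyte_culture",
    "HCC_cell_line",
    "metastasis",
    "biliary",
)
ETIOLOGIES = ("HCV", "HBV", "EtOH", "cryptogenic", "other", "none")
TNM_STAGES = ("T1", "T2", "T3", "T4")

MANIFEST_COLUMNS = ("chromosome", "position", "strand", "gene", "genic_feature", "island_relation")
SAMPLE_SHEET_COLUMNS = (
    "tissue_class",
    "etiology",
    "tnm_stage",
    "differentiation",
    "gender",
    "multifocality",
    "vascularization",
    "tumor_size_class",
    "cirrhosis_flag",
)

AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def chromosome_sort_key(chrom: str) -> tuple[int, int, str]:
    """Sort key giving chr1 < chr2 < ... < chr22 < chrX < chrY < other."""
    m = re.fullmatch(r"(?:chr)?(\d+)", chrom)
    if m:
        return (0, int(m.group(1)), "")
    return (1, 0, chrom)


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        header = fh.readline()
    # tab canonical, comma accepted
    return "\t" if "\t" in header else ","


# ---------------------------------------------------------------------------
# beta matrix


def read_beta_matrix(path: str | Path) -> pd.DataFrame:
    """Read a probes x samples beta-value matrix from delimited text.

    First column holds probe ids, the header row sample ids.  Empty
    fields and the usual NA tokens become missing values.  Values
    outside [0, 1] and duplicated probe ids are hard errors.
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str)
    df.index.name = "probe_id"
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise FormatError(f"duplicate probe_id in beta matrix: {dup[0]!r}")
    na_tokens = {"", "NA", "NaN", "nan", "N/A", "null", "None"}
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        raw = df[col]
        mask_na = raw.isin(na_tokens)
        try:
            vals = pd.to_numeric(raw.where(~mask_na, np.nan))
        except (ValueError, TypeError) as exc:
            raise FormatError(f"non-numeric beta value in column {col!r}: {exc}") from exc
        bad = vals[(vals < 0) | (vals > 1)]
        if len(bad):
            probe = bad.index[0]
            raise FormatError(
                f"beta value {bad.iloc[0]!r} out of [0,1] at probe {probe!r}, sample {col!r}"
            )
        out[col] = vals
    return out


def write_beta_matrix(beta: pd.DataFrame, path: str | Path, float_format: str = "%.6f") -> None:
    beta.to_csv(path, sep="\t", index_label="probe_id", float_format=float_format)


# ---------------------------------------------------------------------------
# probe manifest


def sort_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Canonical, stable (chromosome, position) sort of a manifest."""
    key = manifest["chromosome"].map(chromosome_sort_key)
    order = pd.DataFrame({"k": key, "p": manifest["position"]}).sort_values(
        ["k", "p"], kind="stable"
    )
    return manifest.loc[order.index]


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    dup = manifest.index[manifest.index.duplicated()]
    if len(dup):
        raise FormatError(f"duplicate probe_id in manifest: {dup[0]!r}")
    bad_feat = set(manifest["genic_feature"]) - set(GENIC_FEATURES)
    if bad_feat:
        raise FormatError(
            f"unknown genic_feature {sorted(bad_feat)[0]!r}; allowed: {GENIC_FEATURES}"
        )
    bad_isl = set(manifest["island_relation"]) - set(ISLAND_RELATIONS)
    if bad_isl:
        raise FormatError(
            f"unknown island_relation {sorted(bad_isl)[0]!r}; allowed: {ISLAND_RELATIONS}"
        )
    bad_strand = set(manifest["strand"]) - {"+", "-"}
    if bad_strand:
        raise FormatError(f"unknown strand {sorted(bad_strand)[0]!r}; allowed: '+', '-'")
    if (manifest["position"] < 1).any():
        raise FormatError("manifest positions must be 1-based (>= 1)")
    return manifest


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a probe manifest; returns it validated and canonically sorted.

    Expected columns: probe_id, chr, pos, strand, gene, feature, island
    (long names chromosome/position/genic_feature/island_relation are
    accepted too).
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    rename = {
        "chr": "chromosome",
        "pos": "position",
        "feature": "genic_feature",
        "island": "island_relation",
    }
    df = df.rename(columns=rename)
    missing = {"probe_id", *MANIFEST_COLUMNS} - set(df.columns)
    if missing:
        raise FormatError(f"manifest missing columns: {sorted(missing)}")
    df = df.set_index("probe_id")[list(MANIFEST_COLUMNS)]
    df["position"] = pd.to_numeric(df["position"]).astype(int)
    df["gene"] = df["gene"].fillna("")
    validate_manifest(df)
    return sort_manifest(df)


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    out = manifest.reset_index().rename(
        columns={
            "chromosome": "chr",
            "position": "pos",
            "genic_feature": "feature",
            "island_relation": "island",
        }
    )
    out.to_csv(path, index=False)


def filter_autosomes(manifest: pd.DataFrame) -> pd.DataFrame:
    """Restrict a manifest to chr1..chr22 (the analysis default)."""
    return manifest[manifest["chromosome"].isin(AUTOSOMES)]


# ---------------------------------------------------------------------------
# sample sheet


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    dup = sheet.index[sheet.index.duplicated()]
    if len(dup):
        raise FormatError(f"duplicate sample_id in sample sheet: {dup[0]!r}")
    bad_tc = set(sheet["tissue_class"]) - set(TISSUE_CLASSES)
    if bad_tc:
        raise FormatError(
            f"unknown tissue_class {sorted(bad_tc)[0]!r}; allowed: {TISSUE_CLASSES}"
        )
    bad_et = set(sheet["etiology"]) - set(ETIOLOGIES)
    if bad_et:
        raise FormatError(f"unknown etiology {sorted(bad_et)[0]!r}; allowed: {ETIOLOGIES}")
    staged = sheet["tnm_stage"] != ""
    bad_stage = set(sheet.loc[staged, "tnm_stage"]) - set(TNM_STAGES)
    if bad_stage:
        raise FormatError(f"unknown tnm_stage {sorted(bad_stage)[0]!r}; allowed: {TNM_STAGES}")
    non_hcc = staged & (sheet["tissue_class"] != "HCC")
    if non_hcc.any():
        sid = sheet.index[non_hcc][0]
        raise FormatError(
            f"tnm_stage set on non-HCC sample {sid!r} "
            f"(tissue_class={sheet.loc[sid, 'tissue_class']!r})"
        )
    return sheet


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise FormatError("sample sheet missing 'sample_id' column")
    df = df.set_index("sample_id")
    for col in SAMPLE_SHEET_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    df = df[list(SAMPLE_SHEET_COLUMNS)]
    return validate_sample_sheet(df)


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.reset_index().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# gene models


def read_gene_models(path: str | Path) -> pd.DataFrame:
    """Read gene models (gene, chromosome, strand, tss, tts); tss/tts are
    1-based transcription start/termination positions (tss > tts on the
    minus strand)."""
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = {"gene", "chromosome", "strand", "tss", "tts"} - set(df.columns)
    if missing:
        raise FormatError(f"gene models missing columns: {sorted(missing)}")
    df = df.set_index("gene")
    df["tss"] = pd.to_numeric(df["tss"]).astype(int)
    df["tts"] = pd.to_numeric(df["tts"]).astype(int)
    if (df["tss"] == df["tts"]).any():
        bad = df.index[df["tss"] == df["tts"]][0]
        raise FormatError(f"zero-length gene model {bad!r} (TSS == TTS)")
    return df[["chromosome", "strand", "tss", "tts"]]


def write_gene_models(genes: pd.DataFrame, path: str | Path) -> None:
    genes.reset_index().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# bedGraph / BED export


def export_bedgraph(
    values: Mapping[str, float] | pd.Series,
    manifest: pd.DataFrame,
    path: str | Path,
    track_name: str = "hepmeth",
) -> None:
    """Write per-probe values as a UCSC bedGraph.

    Each probe becomes a length-1 interval [position-1, position) in
    0-based half-open coordinates.  Probes absent from the manifest are
    a hard error.  Output follows manifest (genomic) order.
    """
    values = pd.Series(values, dtype=float)
    missing = values.index.difference(manifest.index)
    if len(missing):
        raise FormatError(f"probe {missing[0]!r} not present in manifest")
    keep = manifest.index.intersection(values.index)
    sub = manifest.loc[keep]
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track_name}"\n')
        for probe, row in sub.iterrows():
            pos = int(row["position"])
            fh.write(f"{row['chromosome']}\t{pos - 1}\t{pos}\t{values[probe]:g}\n")


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Minimal bedGraph reader (round-trip checking and convenience)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            chrom, start, end, value = line.split("\t")
            rows.append((chrom, int(start), int(end), float(value)))
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "value"])


# ---------------------------------------------------------------------------
# call-set JSON


def write_call_set(call_set, path: str | Path) -> None:
    """Serialize a CpGCallSet (see hepmeth.diff) as JSON."""
    payload = {
        "label": call_set.label,
        "fdr_max": call_set.fdr_max,
        "delta_min": call_set.delta_min,
        "hyper": sorted(call_set.hyper),
        "hypo": sorted(call_set.hypo),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_call_set(path: str | Path):
    from .diff import CpGCallSet

    with open(path) as fh:
        payload = json.load(fh)
    return CpGCallSet(
        label=payload["label"],
        hyper=frozenset(payload["hyper"]),
        hypo=frozenset(payload["hypo"]),
        fdr_max=payload["fdr_max"],
        delta_min=payload["delta_min"],
    )
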