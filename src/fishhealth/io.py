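"""Readers and writers for the delimited-text formats the pipeline touches.

All tables are comma-separated UTF-8 with a mandatory header row and a
decimal point. Missing optional numeric cells are written as empty strings;
"NA" is also accepted on read. The full column contract is documented in
docs/file_formats.md. No published raw-table layout exists for this kind of
survey, so the schema here is the package's own.
"""

from __future__ import annotations

import csv
import logging
import math
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import SchemaError, ValidationError
from .model import (
    LESION_CATEGORIES,
    AlignedSequences,
    FishSpecimen,
    HistoProfile,
    Season,
    TreeNode,
)

log = logging.getLogger(__name__)

SPECIMEN_COLUMNS = [
    "id", "species", "season", "length_cm", "weight_g", "liver_weight_g",
    "parasite_count", "thg_ugg", "trophic_level",
]
_REQUIRED_SPECIMEN = [
    "id", "species", "season", "length_cm", "weight_g", "parasite_count",
    "trophic_level",
]


def _parse_float(value, *, row: int, column: str, optional: bool = False):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        value = ""
    text = str(value).strip()
    if text in ("", "NA", "NaN", "nan"):
        if optional:
            return None
        raise ValidationError(f"row {row}: required column {column!r} is empty")
    try:
        return float(text)
    except ValueError:
        raise ValidationError(
            f"row {row}: non-numeric value {text!r} in column {column!r}"
        ) from None


def read_specimen_table(path: str | Path) -> list[FishSpecimen]:
    """Read and validate a specimen table; row numbers are 1-based data rows."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_SPECIMEN if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    specimens: list[FishSpecimen] = []
    for idx, rec in enumerate(df.to_dict("records"), start=1):
        try:
            count = _parse_float(rec["parasite_count"], row=idx,
                                 column="parasite_count")
            if count != int(count):
                raise ValidationError(
                    f"row {idx}: parasite_count {count} is not an integer"
                )
            specimens.append(FishSpecimen(
                id=str(rec["id"]).strip(),
                species=str(rec["species"]).strip(),
                season=Season.parse(rec["season"]),
                length_cm=_parse_float(rec["length_cm"], row=idx,
                                       column="length_cm"),
                weight_g=_parse_float(rec["weight_g"], row=idx,
                                      column="weight_g"),
                liver_weight_g=_parse_float(rec.get("liver_weight_g", ""),
                                            row=idx, column="liver_weight_g",
                                            optional=True),
                parasite_count=int(count),
                thg_ugg=_parse_float(rec.get("thg_ugg", ""), row=idx,
                                     column="thg_ugg", optional=True),
                trophic_level=_parse_float(rec["trophic_level"], row=idx,
                                           column="trophic_level"),
            ))
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {idx}: {exc}") from None
    log.info("read %d specimens from %s (0 rejected)", len(specimens), path)
    return specimens


def write_specimen_table(specimens: list[FishSpecimen], path: str | Path) -> None:
    def cell(x):
        return "" if x is None else format(x, ".6g") if isinstance(x, float) else x

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SPECIMEN_COLUMNS)
        for s in specimens:
            writer.writerow([
                s.id, s.species, s.season.value, cell(s.length_cm),
                cell(s.weight_g), cell(s.liver_weight_g), s.parasite_count,
                cell(s.thg_ugg), cell(s.trophic_level),
            ])


def read_histology_table(path: str | Path) -> list[HistoProfile]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ("specimen_id", "species", *LESION_CATEGORIES)
               if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    profiles = []
    for idx, rec in enumerate(df.to_dict("records"), start=1):
        scores = {}
        for cat in LESION_CATEGORIES:
            val = _parse_float(rec[cat], row=idx, column=cat)
            if val != int(val):
                raise ValidationError(
                    f"{path}: row {idx}: score {val} for {cat} is not an integer"
                )
            scores[cat] = int(val)
        try:
            profiles.append(HistoProfile(
                specimen_id=str(rec["specimen_id"]).strip(),
                species=str(rec["species"]).strip(),
                scores=scores,
            ))
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {idx}: {exc}") from None
    return profiles


def write_histology_table(profiles: list[HistoProfile], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["specimen_id", "species", *LESION_CATEGORIES])
        for p in profiles:
            writer.writerow([p.specimen_id, p.species,
                             *[p.scores[c] for c in LESION_CATEGORIES]])


QC_COLUMNS = ["kind", "sample_id", "value", "reference"]


def read_qc_table(path: str | Path) -> pd.DataFrame:
    """QC readings: kind in {blank, crm, sample, calibration}, values in ug/g.

    ``sample_id`` groups duplicate sample readings; ``reference`` holds the
    certified value for CRM rows and the nominal concentration for
    calibration rows.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("kind", "value") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    for col in ("sample_id", "reference"):
        if col not in df.columns:
            df[col] = pd.NA
    bad = set(df["kind"]) - {"blank", "crm", "sample", "calibration"}
    if bad:
        raise ValidationError(f"{path}: unknown QC row kind(s) {sorted(bad)}")
    return df[QC_COLUMNS]


def write_qc_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=QC_COLUMNS)


def read_fasta(path: str | Path) -> AlignedSequences:
    """Read a pre-aligned FASTA file; sequences are uppercased and
    length-checked (ragged input raises ``AlignmentError``)."""
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValidationError(f"{path}: no FASTA records found")
    return AlignedSequences(records)


def write_fasta(seqs: AlignedSequences, path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=sid, description="") for sid, s in seqs.records]
    with open(path, "w", encoding="utf-8") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=70)
        writer.write_file(records)


def write_newick(tree: TreeNode, path: str | Path) -> None:
    Path(path).write_text(tree.newick() + "\n", encoding="utf-8")


def read_newick(path_or_string: str | Path) -> TreeNode:
    """Parse newick via dendropy and convert to the package tree type."""
    import dendropy

    text = str(path_or_string)
    if not text.strip().startswith("(") and Path(text).exists():
        text = Path(text).read_text(encoding="utf-8")
    dtree = dendropy.Tree.get(data=text, schema="newick")

    def convert(dnode) -> TreeNode:
        children = [convert(c) for c in dnode.child_nodes()]
        name = dnode.taxon.label if dnode.taxon else dnode.label
        support = None
        if children and name is not None:
            try:
                support = int(float(name))
                name = None
            except ValueError:
                pass
        return TreeNode(name=name, length=dnode.edge.length,
                        children=children, support=support)

    return convert(dtree.seed_node)
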