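"""Readers and writers for every on-disk format used by the pipeline.

Formats (all plain text, documented in ``docs/formats.md``):

* plate table TSV — one row per grid position, 1-based row/col, top-left
  origin, arbitrary size units (pixel area);
* genome BED — standard 6-column BED, 0-based half-open;
* layout TSV — position -> (block, kind, gene);
* truth TSV — planted effects of the simulator;
* GMT — gene-set collections (term, description, members);
* disease slim TSV — (disease_id, disease_name, gene_id) triples;
* YAML configuration (see :mod:`sgafit.config`).

All readers are total on their writers' output (round-trip identity) and
report malformed rows with their line numbers.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .config import Config, config_from_dict
from .errors import ConfigError, ScreenFormatError

logger = logging.getLogger(__name__)

PLATE_COLUMNS = ["batch", "query", "plate", "row", "col", "size", "position_kind", "gene_id"]
LAYOUT_COLUMNS = ["plate", "row", "col", "block_id", "position_kind", "gene_id", "control_empty"]
GENOME_COLUMNS = ["gene_id", "chromosome", "start", "end", "strand"]
TRUTH_COLUMNS = ["gene_id", "query", "delta", "linked"]

_NA = "."  # missing-field marker in TSVs


@dataclass(frozen=True)
class GeneSet:
    """A named gene set from an annotation collection (GMT line)."""

    term_id: str
    term_name: str
    genes: frozenset[str]


def _data_lines(path):
    """Yield (line_number, fields) for non-comment, non-blank TSV lines."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_plate_table(path) -> pd.DataFrame:
    """Read a colony-size table; validates positions, sizes and gene labels."""
    rows, header = [], None
    for lineno, fields in _data_lines(path):
        if header is None:
            header = fields
            if header != PLATE_COLUMNS:
                raise ScreenFormatError(
                    f"{path}: line {lineno}: expected header {PLATE_COLUMNS}, got {header}"
                )
            continue
        if len(fields) != len(PLATE_COLUMNS):
            raise ScreenFormatError(
                f"{path}: line {lineno}: expected {len(PLATE_COLUMNS)} fields, got {len(fields)}"
            )
        batch, query, plate, row, col, size, kind, gene = fields
        try:
            row_i, col_i, size_f = int(row), int(col), float(size)
        except ValueError as exc:
            raise ScreenFormatError(f"{path}: line {lineno}: {exc}") from None
        if size_f < 0:
            raise ScreenFormatError(f"{path}: line {lineno}: negative size {size}")
        if kind not in ("library", "empty", "reference"):
            raise ScreenFormatError(f"{path}: line {lineno}: bad position_kind '{kind}'")
        gene_val = None if gene == _NA else gene
        if (gene_val is not None) != (kind == "library"):
            raise ScreenFormatError(
                f"{path}: line {lineno}: gene_id must be present iff position_kind=library"
            )
        rows.append((batch, query, plate, row_i, col_i, size_f, kind, gene_val))
    table = pd.DataFrame(rows, columns=PLATE_COLUMNS)
    if table.duplicated(subset=["batch", "query", "plate", "row", "col"]).any():
        dup = table[table.duplicated(subset=["batch", "query", "plate", "row", "col"])].iloc[0]
        raise ScreenFormatError(
            f"{path}: duplicate position ({dup.batch}, {dup['query']}, {dup.plate}, "
            f"{dup.row}, {dup.col})"
        )
    return table


def write_plate_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out["gene_id"] = out["gene_id"].where(out["gene_id"].notna(), _NA)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_genome_bed(path) -> pd.DataFrame:
    """Read a 6-column BED (0-based half-open) into a genome map."""
    rows = []
    for lineno, fields in _data_lines(path):
        if fields[0] in ("track", "browser") or fields[0].startswith(("track ", "browser ")):
            continue
        if len(fields) < 6:
            raise ScreenFormatError(f"{path}: line {lineno}: need 6 BED columns")
        chrom, start, end, name, _score, strand = fields[:6]
        try:
            start_i, end_i = int(start), int(end)
        except ValueError as exc:
            raise ScreenFormatError(f"{path}: line {lineno}: {exc}") from None
        if start_i >= end_i:
            raise ScreenFormatError(f"{path}: line {lineno}: start >= end")
        if strand not in ("+", "-"):
            raise ScreenFormatError(f"{path}: line {lineno}: bad strand '{strand}'")
        rows.append((name, chrom, start_i, end_i, strand))
    genome = pd.DataFrame(rows, columns=GENOME_COLUMNS)
    if genome["gene_id"].duplicated().any():
        dup = genome.loc[genome["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ScreenFormatError(f"{path}: duplicate gene_id '{dup}'")
    return genome


def write_genome_bed(genome: pd.DataFrame, path) -> None:
    bed = genome[["chromosome", "start", "end", "gene_id"]].copy()
    bed["score"] = 0
    bed["strand"] = genome["strand"].values
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_layout(path) -> pd.DataFrame:
    rows, header = [], None
    for lineno, fields in _data_lines(path):
        if header is None:
            header = fields
            if header != LAYOUT_COLUMNS:
                raise ScreenFormatError(
                    f"{path}: line {lineno}: expected header {LAYOUT_COLUMNS}"
                )
            continue
        plate, row, col, block, kind, gene, ctrl_empty = fields
        rows.append((int(plate), int(row), int(col), block, kind,
                     None if gene == _NA else gene, ctrl_empty == "1"))
    return pd.DataFrame(rows, columns=LAYOUT_COLUMNS)


def write_layout(layout: pd.DataFrame, path) -> None:
    out = layout.copy()
    out["gene_id"] = out["gene_id"].where(out["gene_id"].notna(), _NA)
    out["control_empty"] = out["control_empty"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", comment="#")
    missing = set(TRUTH_COLUMNS) - set(table.columns)
    if missing:
        raise ScreenFormatError(f"{path}: missing truth columns {sorted(missing)}")
    table["linked"] = table["linked"].astype(bool)
    return table[TRUTH_COLUMNS]


def write_truth(truth: pd.DataFrame, path) -> None:
    out = truth[TRUTH_COLUMNS].copy()
    out["linked"] = out["linked"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict[str, GeneSet]:
    """Read a GMT gene-set collection; empty terms are dropped with a warning."""
    sets: dict[str, GeneSet] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise ScreenFormatError(f"{path}: line {lineno}: need term, description, genes...")
        term_id, term_name, *genes = fields
        genes = frozenset(g for g in genes if g)
        if term_id in sets:
            raise ScreenFormatError(f"{path}: line {lineno}: duplicate term '{term_id}'")
        if not genes:
            logger.warning("%s: line %d: term '%s' has no genes, dropped", path, lineno, term_id)
            continue
        sets[term_id] = GeneSet(term_id, term_name, genes)
    return sets


def write_gmt(sets: dict[str, GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in sets.values():
            fh.write("\t".join([gs.term_id, gs.term_name, *sorted(gs.genes)]) + "\n")


def read_disease_slim(path) -> dict[str, GeneSet]:
    """Read a (disease_id, disease_name, gene_id) TSV into disease gene sets.

    A gene may appear under several diseases; duplicates within one disease
    collapse to set membership.
    """
    names: dict[str, str] = {}
    members: dict[str, set[str]] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) != 3:
            raise ScreenFormatError(f"{path}: line {lineno}: need 3 columns")
        disease_id, disease_name, gene = fields
        if disease_id in names and names[disease_id] != disease_name:
            raise ScreenFormatError(
                f"{path}: line {lineno}: conflicting names for '{disease_id}'"
            )
        names[disease_id] = disease_name
        members.setdefault(disease_id, set()).add(gene)
    return {
        did: GeneSet(did, names[did], frozenset(genes)) for did, genes in members.items()
    }


def write_disease_slim(slim: dict[str, GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in slim.values():
            for gene in sorted(gs.genes):
                fh.write(f"{gs.term_id}\t{gs.term_name}\t{gene}\n")


def load_config(path) -> Config:
    """Load, validate and resolve a YAML configuration file.

    Unknown keys are rejected; defaults (alpha, linkage window, enrichment
    FDR, simulator parameters) are filled in.  The fully resolved
    configuration is echoed to the log.
    """
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML: {exc}") from None
    cfg = config_from_dict(data)
    logger.info("resolved configuration from %s: %s", path, cfg.to_dict())
    return cfg


def save_config(cfg: Config, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def file_sha256(path) -> str:
    """Hex digest of a file, recorded in run manifests for provenance."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
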