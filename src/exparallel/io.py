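"""Readers and writers for the tabular artifacts the pipeline touches.

All formats are plain TSV (counts, design, DE tables, pairwise statistics) or
GMT (gene sets); every writer round-trips exactly through its reader.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .model import DESIGN_COLUMNS, CountMatrix, DETable, ExparallelError, GeneSetCollection, SampleDesign

log = logging.getLogger(__name__)


def read_counts(path) -> CountMatrix:
    """Read a genes x samples TSV: header row of sample ids, first column gene ids,
    integer cells.  Non-integer or negative cells raise, naming the offender."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    out = {}
    for col in df.columns:
        try:
            out[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            gene = bad.index[0] if len(bad) else "?"
            raise ExparallelError(
                f"non-numeric count for gene {gene!r}, sample {col!r} in {path}"
            ) from exc
    num = pd.DataFrame(out, index=df.index)
    for col in num.columns:
        vals = num[col]
        if vals.dtype.kind == "f":
            frac = vals[vals != vals.round()]
            if len(frac):
                raise ExparallelError(
                    f"non-integer count for gene {frac.index[0]!r}, sample {col!r} in {path}"
                )
            num[col] = vals.astype("int64")
    return CountMatrix(num.astype("int64"))


def write_counts(cm: CountMatrix, path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene_id")


def read_design(path) -> SampleDesign:
    """Read the 5-column sample design TSV (sample_id, level, lineage_id,
    subreplicate_id, state); level/state strings are validated and normalized."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise ExparallelError(f"design file {path} missing columns {missing}")
    return SampleDesign(df)


def write_design(design: SampleDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def read_detable(path, unit_id: str | None = None, level: str | None = None) -> DETable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DETable(unit_id or Path(path).stem, df, level=level)


def write_detable(de: DETable, path) -> None:
    de.table.to_csv(path, sep="\t", index_label="gene_id")


def _read_gene_sets_tsv(path) -> GeneSetCollection:
    sets: dict[str, set] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ExparallelError(
                    f"unparseable gene-set line {lineno} in {path}: {line!r} "
                    "(expected gene_id<TAB>set_id)"
                )
            gene, sid = parts
            if gene == "gene_id" and sid == "set_id" and lineno == 1:
                continue  # optional header
            sets.setdefault(sid, set()).add(gene)
    return GeneSetCollection({sid: frozenset(m) for sid, m in sets.items()})


def _read_gene_sets_gmt(path) -> GeneSetCollection:
    sets: dict[str, frozenset] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ExparallelError(
                    f"unparseable GMT line {lineno} in {path}: need id, description, "
                    ">=1 member"
                )
            sid, desc, *members = parts
            members = [m for m in members if m]
            if not members:
                raise ExparallelError(f"GMT line {lineno} in {path} has no members")
            sets[sid] = frozenset(members)
            names[sid] = desc or sid
    return GeneSetCollection(sets, names)


def read_gene_sets(path, universe=None) -> GeneSetCollection:
    """Read gene sets from a two-column TSV (gene_id, set_id) or a GMT file
    (chosen by the .gmt suffix).  When ``universe`` is given, members are
    intersected with it and sets emptied by the intersection are dropped."""
    if str(path).endswith(".gmt"):
        coll = _read_gene_sets_gmt(path)
    else:
        coll = _read_gene_sets_tsv(path)
    if universe is not None:
        coll = coll.restrict_to_universe(universe)
    return coll


def write_gene_sets(coll: GeneSetCollection, path) -> None:
    """Write as two-column TSV (gene_id, set_id), sorted for determinism."""
    with open(path, "w") as fh:
        fh.write("gene_id\tset_id\n")
        for sid in sorted(coll):
            for gene in sorted(coll.members(sid)):
                fh.write(f"{gene}\t{sid}\n")
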