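"""Readers and writers for the external formats the pipeline touches.

Every downstream stage consumes only the typed containers defined here:
MaxQuant-style protein-group tables, matrisome reference lists, GMT gene-set
collections, STRING-style weighted edge lists and plain one-symbol-per-line
gene lists.  Parsing is delegated to pandas; this module adds the domain
validation (flag removal, symbol normalization, dialect handling) and nothing
else.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger("matrisomics")

# Fraction labels used throughout the pipeline.
ECM = "ECM"
CELLULAR = "CELLULAR"

# Matrisome controlled vocabulary: category -> division.
CORE_MATRISOME = "Core matrisome"
MATRISOME_ASSOCIATED = "Matrisome-associated"
NON_MATRISOME = "non-matrisome"
CATEGORY_DIVISION = {
    "Collagens": CORE_MATRISOME,
    "ECM Glycoproteins": CORE_MATRISOME,
    "Proteoglycans": CORE_MATRISOME,
    "ECM-affiliated Proteins": MATRISOME_ASSOCIATED,
    "ECM Regulators": MATRISOME_ASSOCIATED,
    "Secreted Factors": MATRISOME_ASSOCIATED,
}


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class DesignError(ValueError):
    """Sample design and data file disagree."""


def normalize_symbol(raw: str, species: str) -> str:
    """Normalize a gene symbol: first token of a semicolon list, species case.

    Human symbols are uppercased; mouse symbols are capitalized
    (first letter upper, rest lower), the standard MGI convention.  Returns
    the empty string when nothing remains after stripping.
    """
    first = str(raw).split(";")[0].strip()
    if not first or first.lower() == "nan":
        return ""
    if species == "human":
        return first.upper()
    if species == "mouse":
        return first[0].upper() + first[1:].lower()
    raise ValueError(f"unknown species {species!r}")


# ---------------------------------------------------------------------------
# Sample design and protein-group tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleInfo:
    fraction: str
    replicate: int
    subject: str = ""


@dataclass
class SampleDesign:
    """Maps sample ids to (fraction, replicate, subject)."""

    samples: dict[str, SampleInfo]

    def validate(self, require_both: bool = True) -> None:
        seen: set[tuple[str, int]] = set()
        for sid, info in self.samples.items():
            key = (info.fraction, info.replicate)
            if key in seen:
                raise DesignError(f"duplicate (fraction, replicate) {key} in design")
            seen.add(key)
        fractions = {i.fraction for i in self.samples.values()}
        if require_both and not {ECM, CELLULAR} <= fractions:
            raise DesignError(f"design must contain both fractions, got {sorted(fractions)}")

    def sample_ids(self, fraction: str) -> list[str]:
        """Sample ids of one fraction, ordered by replicate number."""
        pairs = [(i.replicate, s) for s, i in self.samples.items() if i.fraction == fraction]
        return [s for _, s in sorted(pairs)]

    def n_replicates(self, fraction: str) -> int:
        return len(self.sample_ids(fraction))

    @property
    def fractions(self) -> set[str]:
        return {i.fraction for i in self.samples.values()}


def read_design(path: str | Path) -> SampleDesign:
    """Read a sample design TSV with columns sample, fraction, replicate[, subject]."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample", "fraction", "replicate"):
        if col not in df.columns:
            raise FormatError(f"design file missing column {col!r}")
    samples = {}
    for _, row in df.iterrows():
        samples[str(row["sample"])] = SampleInfo(
            fraction=str(row["fraction"]),
            replicate=int(row["replicate"]),
            subject=str(row.get("subject", "")),
        )
    design = SampleDesign(samples)
    design.validate(require_both=False)
    return design


@dataclass
class ProteinGroup:
    group_id: str
    gene_symbol: str
    species: str
    unique_peptides: int
    intensity: dict[str, float]
    lfq_intensity: dict[str, float]
    is_contaminant: bool = False
    is_reverse: bool = False

    def __post_init__(self) -> None:
        if set(self.intensity) != set(self.lfq_intensity):
            raise DesignError(f"{self.group_id}: intensity and LFQ sample ids differ")
        for m in (self.intensity, self.lfq_intensity):
            for sid, v in m.items():
                if v < 0:
                    raise FormatError(f"{self.group_id}: negative intensity in {sid}")


@dataclass
class ProteinGroupTable:
    rows: list[ProteinGroup]
    design: SampleDesign
    # Rows whose gene symbol was empty after normalization; kept for reporting.
    unmapped: list[ProteinGroup] = field(default_factory=list)
    dropped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.group_id for r in self.rows]
        if len(ids) != len(set(ids)):
            raise FormatError("duplicate group_id in protein table")

    def __len__(self) -> int:
        return len(self.rows)

    def symbols(self) -> list[str]:
        return [r.gene_symbol for r in self.rows]

    def by_symbol(self) -> dict[str, ProteinGroup]:
        return {r.gene_symbol: r for r in self.rows}

    def subset(self, keep_ids: Iterable[str]) -> "ProteinGroupTable":
        keep = set(keep_ids)
        return ProteinGroupTable(
            rows=[r for r in self.rows if r.group_id in keep],
            design=self.design,
        )

    def values(self, row: ProteinGroup, fraction: str, kind: str = "lfq") -> list[float]:
        """Per-replicate values of one protein in one fraction, replicate order."""
        m = row.lfq_intensity if kind == "lfq" else row.intensity
        return [m[s] for s in self.design.sample_ids(fraction)]

    def to_frame(self, kind: str = "lfq") -> pd.DataFrame:
        """Wide matrix: group_id x sample id."""
        cols = list(self.design.samples)
        data = {
            r.group_id: [(r.lfq_intensity if kind == "lfq" else r.intensity)[c] for c in cols]
            for r in self.rows
        }
        return pd.DataFrame.from_dict(data, orient="index", columns=cols)


@dataclass(frozen=True)
class ColumnConfig:
    """Column names of the protein-group dialect (MaxQuant defaults)."""

    gene_symbol: str = "Gene names"
    unique_peptides: str = "Unique peptides"
    reverse: str = "Reverse"
    contaminant: str = "Potential contaminant"
    intensity_prefix: str = "Intensity "
    lfq_prefix: str = "LFQ intensity "
    id_column: str = "id"


def _flagged(value) -> bool:
    return str(value).strip() in {"+", "1", "True", "true", "yes"}


def read_protein_groups(
    path: str | Path,
    design: SampleDesign,
    columns: ColumnConfig = ColumnConfig(),
    species: str = "human",
) -> ProteinGroupTable:
    """Read a MaxQuant-style proteinGroups TSV into a typed table.

    Reverse-database hits and contaminants are removed here (counts recorded on
    the returned table), empty intensity cells become 0 (non-detection), and
    gene symbols collapse to the first token of semicolon lists.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (columns.gene_symbol, columns.unique_peptides):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r}")
    for sid in design.samples:
        for prefix in (columns.intensity_prefix, columns.lfq_prefix):
            if prefix + sid not in df.columns:
                raise DesignError(f"sample {sid!r} missing column {prefix + sid!r}")

    dropped = {"reverse": 0, "contaminant": 0}
    rows: list[ProteinGroup] = []
    unmapped: list[ProteinGroup] = []
    for i, rec in df.iterrows():
        if columns.reverse in df.columns and _flagged(rec[columns.reverse]):
            dropped["reverse"] += 1
            continue
        if columns.contaminant in df.columns and _flagged(rec[columns.contaminant]):
            dropped["contaminant"] += 1
            continue
        gid = str(rec[columns.id_column]) if columns.id_column in df.columns else str(i)
        intensity = {}
        lfq = {}
        for sid in design.samples:
            raw = rec[columns.intensity_prefix + sid]
            lfq_raw = rec[columns.lfq_prefix + sid]
            intensity[sid] = float(raw) if pd.notna(raw) and str(raw).strip() else 0.0
            lfq[sid] = float(lfq_raw) if pd.notna(lfq_raw) and str(lfq_raw).strip() else 0.0
        group = ProteinGroup(
            group_id=gid,
            gene_symbol=normalize_symbol(rec[columns.gene_symbol], species),
            species=species,
            unique_peptides=int(float(rec[columns.unique_peptides])),
            intensity=intensity,
            lfq_intensity=lfq,
        )
        if group.gene_symbol:
            rows.append(group)
        else:
            unmapped.append(group)
    if not rows:
        raise FormatError(f"no usable rows in {path}")
    logger.info(
        "loaded %d protein groups from %s (dropped %d reverse, %d contaminant, %d unmapped)",
        len(rows), path, dropped["reverse"], dropped["contaminant"], len(unmapped),
    )
    table = ProteinGroupTable(rows=rows, design=design)
    table.unmapped = unmapped
    table.dropped = dropped
    return table


# ---------------------------------------------------------------------------
# Matrisome reference
# ---------------------------------------------------------------------------

@dataclass
class MatrisomeReference:
    """Species-specific map symbol -> (division, category) + basement-membrane set."""

    entries: dict[str, tuple[str, str]]
    bm_genes: set[str]
    species: str

    def __post_init__(self) -> None:
        for sym, (division, category) in self.entries.items():
            expected = CATEGORY_DIVISION.get(category)
            if expected is None:
                raise FormatError(
                    f"{sym}: unknown category {category!r}; allowed: "
                    f"{sorted(CATEGORY_DIVISION)}"
                )
            if division != expected:
                raise FormatError(
                    f"{sym}: category {category!r} implies division {expected!r}, "
                    f"got {division!r}"
                )
        stray = self.bm_genes - set(self.entries)
        if stray:
            raise FormatError(f"basement-membrane genes not in reference: {sorted(stray)}")


def read_matrisome_reference(
    path: str | Path,
    species: str,
    bm_path: str | Path | None = None,
) -> MatrisomeReference:
    """Read a matrisome list (CSV or TSV; columns gene/symbol, division, category)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.strip().lower() for c in df.columns]
    sym_col = "gene" if "gene" in df.columns else "symbol"
    for col in (sym_col, "division", "category"):
        if col not in df.columns:
            raise FormatError(f"matrisome reference missing column {col!r}")
    entries: dict[str, tuple[str, str]] = {}
    for _, row in df.iterrows():
        sym = normalize_symbol(row[sym_col], species)
        if sym in entries:
            logger.warning("duplicate matrisome symbol %s; keeping first occurrence", sym)
            continue
        entries[sym] = (str(row["division"]).strip(), str(row["category"]).strip())
    bm: set[str] = set()
    if bm_path is not None:
        bm = {normalize_symbol(s, species) for s in read_gene_list(bm_path)}
    return MatrisomeReference(entries=entries, bm_genes=bm, species=species)


# ---------------------------------------------------------------------------
# Gene sets, gene lists, edge lists
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Ordered map set_id -> (name, frozenset of symbols)."""

    sets: dict[str, tuple[str, frozenset[str]]]

    def union(self) -> set[str]:
        out: set[str] = set()
        for _, members in self.sets.values():
            out |= members
        return out

    def __len__(self) -> int:
        return len(self.sets)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: set_id TAB description TAB symbol [TAB symbol ...]."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            set_id, name = fields[0], fields[1]
            if set_id in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set id {set_id!r}")
            members = frozenset(s.strip().upper() for s in fields[2:] if s.strip())
            if not members:
                logger.warning("GMT set %s is empty; dropped", set_id)
                continue
            sets[set_id] = (name, members)
    return GeneSetCollection(sets=sets)


def read_gene_list(path: str | Path) -> set[str]:
    """Read a plain list, one symbol per line; blank lines and # comments ignored."""
    out = set()
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s and not s.startswith("#"):
                out.add(s)
    return out


@dataclass
class EdgeList:
    edges: list[tuple[str, str, float]]

    def __len__(self) -> int:
        return len(self.edges)


def read_edge_list(path: str | Path, score_dialect: str = "auto") -> EdgeList:
    """Read a weighted edge TSV (STRING export dialect).

    ``per_mille`` scores (STRING's 0-999 integers) are divided by 1000;
    ``auto`` chooses per_mille when any score exceeds 1.  Self-edges are
    dropped, undirected duplicates merged keeping the max score.
    """
    if score_dialect not in {"unit", "per_mille", "auto"}:
        raise ValueError(f"unknown score dialect {score_dialect!r}")
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 3:
        raise FormatError("edge list needs two node columns and a score column")
    a, b, score = df.columns[0], df.columns[1], df.columns[2]
    scores = df[score].astype(float)
    if (scores < 0).any():
        raise FormatError("negative score in edge list")
    if score_dialect == "per_mille" or (score_dialect == "auto" and scores.max() > 1):
        scores = scores / 1000.0
    scores = scores.clip(0.0, 1.0)
    merged: dict[tuple[str, str], float] = {}
    for na, nb, s in zip(df[a].astype(str), df[b].astype(str), scores):
        if na == nb:
            continue
        key = (na, nb) if na < nb else (nb, na)
        merged[key] = max(merged.get(key, 0.0), float(s))
    return EdgeList(edges=[(na, nb, s) for (na, nb), s in merged.items()])


# ---------------------------------------------------------------------------
# Result writing
# ---------------------------------------------------------------------------

def write_results(
    tables: Mapping[str, pd.DataFrame] | Iterable[tuple[str, pd.DataFrame]],
    out_dir: str | Path,
    config: Mapping | None = None,
) -> dict:
    """Write named result tables as TSV plus a JSON manifest.

    Returns the manifest (also written to ``manifest.json``): file names, row
    counts and a snapshot of the run configuration.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs = list(tables.items()) if isinstance(tables, Mapping) else list(tables)
    names = [n for n, _ in pairs]
    if len(names) != len(set(names)):
        raise ValueError("duplicate table name in results")
    manifest: dict = {"files": [], "config": dict(config or {})}
    for name, df in pairs:
        fname = f"{name}.tsv"
        df.to_csv(out_dir / fname, sep="\t", index=False)
        manifest["files"].append({"name": name, "file": fname, "rows": int(len(df))})
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
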