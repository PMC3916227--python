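"""Domain types and tab-separated readers/writers.

Gene identity throughout the package is the bare symbol string: the mutation
table, the interaction network, the length table and any gene lists are all
expected to share one symbol namespace (CCDS-style symbols in typical use).
Symbols are whitespace-trimmed on input; case is preserved; no alias
resolution is attempted. Mismatches between files are diagnosed by the
pipeline with log messages, never fatally.

Genomic positions are 1-based. Mutation identity for recurrence purposes is
the coordinate pair ``(chrom, pos)`` only — alleles and strand are ignored.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file does not match its expected tabular format."""


class RowError(ValueError):
    """A single data row could not be parsed (message carries line number)."""


class VariantClass(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    NONSTOP = "nonstop"
    SPLICE_SITE = "splice_site"
    TRANSLATION_START = "translation_start"
    SILENT = "silent"
    DNP_NONSILENT = "DNP_nonsilent"
    TNP_NONSILENT = "TNP_nonsilent"
    FRAMESHIFT_INDEL = "frameshift_indel"
    INFRAME_INDEL = "inframe_indel"
    OTHER_NONCODING = "other_noncoding"


#: Common MAF spellings mapped onto the internal classification. Anything
#: not listed here parses as ``other_noncoding`` (and is therefore never
#: counted as deleterious).
CLASS_ALIASES: dict[str, VariantClass] = {
    "missense": VariantClass.MISSENSE,
    "missense_mutation": VariantClass.MISSENSE,
    "nonsense": VariantClass.NONSENSE,
    "nonsense_mutation": VariantClass.NONSENSE,
    "nonstop": VariantClass.NONSTOP,
    "nonstop_mutation": VariantClass.NONSTOP,
    "splice_site": VariantClass.SPLICE_SITE,
    "translation_start": VariantClass.TRANSLATION_START,
    "translation_start_site": VariantClass.TRANSLATION_START,
    "silent": VariantClass.SILENT,
    "dnp_nonsilent": VariantClass.DNP_NONSILENT,
    "tnp_nonsilent": VariantClass.TNP_NONSILENT,
    "frameshift_indel": VariantClass.FRAMESHIFT_INDEL,
    "frame_shift_del": VariantClass.FRAMESHIFT_INDEL,
    "frame_shift_ins": VariantClass.FRAMESHIFT_INDEL,
    "inframe_indel": VariantClass.INFRAME_INDEL,
    "in_frame_del": VariantClass.INFRAME_INDEL,
    "in_frame_ins": VariantClass.INFRAME_INDEL,
    "other_noncoding": VariantClass.OTHER_NONCODING,
}


@dataclass(frozen=True)
class MutationRecord:
    """One annotated somatic variant observed in one sample."""

    sample_id: str
    gene: str
    chrom: str
    pos: int
    variant_class: VariantClass
    sift: Optional[float] = None
    polyphen2: Optional[float] = None
    is_known_snp: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for name in ("sift", "polyphen2"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} score {v} outside [0, 1]")

    @property
    def site(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass
class SampleProfile:
    """Per-sample set of mutated genes with their deleterious-mutation sites.

    ``sites[g]`` is a multiset (list) of ``(chrom, pos)`` coordinates; a gene
    appears in ``sites`` iff it appears in ``mutgenes``.
    """

    sample_id: str
    mutgenes: set[str] = field(default_factory=set)
    sites: dict[str, list[tuple[str, int]]] = field(default_factory=dict)

    def add_site(self, gene: str, site: tuple[str, int]) -> None:
        self.mutgenes.add(gene)
        self.sites.setdefault(gene, []).append(site)

    def n_mutgenes(self) -> int:
        return len(self.mutgenes)


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols (anchor lists, benchmark lists, ...)."""

    name: str
    members: frozenset[str]

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def __len__(self) -> int:
        return len(self.members)

    def intersect(self, universe: Iterable[str]) -> "GeneSet":
        return GeneSet(self.name, frozenset(self.members) & frozenset(universe))


@dataclass(frozen=True)
class MafDialect:
    """Column-name mapping for MAF-like mutation tables."""

    sample: str = "Tumor_Sample_Barcode"
    gene: str = "Hugo_Symbol"
    chrom: str = "Chromosome"
    pos: str = "Start_Position"
    variant_class: str = "Variant_Classification"
    sift: str = "SIFT"
    polyphen2: str = "PolyPhen2"
    is_known_snp: str = "is_known_snp"


DEFAULT_DIALECT = MafDialect()


def _parse_score(raw: str) -> Optional[float]:
    raw = raw.strip()
    if raw in ("", ".", "NA", "NaN", "nan", "None"):
        return None
    return float(raw)


def read_mutations(
    path: str | Path,
    dialect: MafDialect = DEFAULT_DIALECT,
    drop_known_snps: bool = True,
) -> list[MutationRecord]:
    """Read a tab-separated MAF-like mutation table.

    Mandatory columns (per the dialect): sample, gene, chromosome, position,
    variant classification. SIFT/PolyPhen2 columns are optional; absent or
    blank scores become ``None``, never zero. Rows whose classification is
    not recognized map to ``other_noncoding``. Rows flagged in an optional
    boolean known-SNP column are dropped (with a logged count) when
    ``drop_known_snps`` is true.
    """
    path = Path(path)
    records: list[MutationRecord] = []
    n_snp_dropped = 0
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected a header row")
        header = [h.strip() for h in header]
        col = {name: i for i, name in enumerate(header)}
        mandatory = {
            "sample": dialect.sample,
            "gene": dialect.gene,
            "chromosome": dialect.chrom,
            "position": dialect.pos,
            "variant classification": dialect.variant_class,
        }
        for role, name in mandatory.items():
            if name not in col:
                raise FormatError(
                    f"{path}: missing mandatory column {name!r} ({role})"
                )
        i_sift = col.get(dialect.sift)
        i_poly = col.get(dialect.polyphen2)
        i_snp = col.get(dialect.is_known_snp)

        for lineno, row in enumerate(reader, start=2):
            if not row or all(not f.strip() for f in row):
                continue
            try:
                pos = int(row[col[dialect.pos]])
            except (ValueError, IndexError) as exc:
                raise RowError(
                    f"{path}:{lineno}: unparsable position "
                    f"{row[col[dialect.pos]] if len(row) > col[dialect.pos] else '<missing>'!r}"
                ) from exc
            vc_raw = row[col[dialect.variant_class]].strip()
            vclass = CLASS_ALIASES.get(vc_raw.lower(), VariantClass.OTHER_NONCODING)
            try:
                sift = _parse_score(row[i_sift]) if i_sift is not None and i_sift < len(row) else None
                poly = _parse_score(row[i_poly]) if i_poly is not None and i_poly < len(row) else None
            except ValueError as exc:
                raise RowError(f"{path}:{lineno}: unparsable score") from exc
            known = False
            if i_snp is not None and i_snp < len(row):
                known = row[i_snp].strip().lower() in ("1", "true", "yes", "y")
            if known and drop_known_snps:
                n_snp_dropped += 1
                continue
            records.append(
                MutationRecord(
                    sample_id=row[col[dialect.sample]].strip(),
                    gene=row[col[dialect.gene]].strip(),
                    chrom=row[col[dialect.chrom]].strip(),
                    pos=pos,
                    variant_class=vclass,
                    sift=sift,
                    polyphen2=poly,
                    is_known_snp=known,
                )
            )
    if n_snp_dropped:
        log.info("%s: dropped %d known-SNP rows", path, n_snp_dropped)
    return records


_EDGE_HEADER_TOKENS = {
    "genea", "geneb", "gene_a", "gene_b", "protein1", "protein2",
    "proteina", "proteinb", "source", "target", "node1", "node2",
}


def read_network(path: str | Path) -> nx.Graph:
    """Read an undirected edge list (two tab-separated symbol columns).

    Self-loops are dropped (logged); duplicate edges collapse; extra columns
    beyond the first two are ignored. An optional header row using common
    edge-table names is skipped.
    """
    path = Path(path)
    g = nx.Graph()
    n_self = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise FormatError(f"{path}:{lineno}: expected >=2 tab-separated columns")
            a, b = fields[0], fields[1]
            if lineno == 1 and (a.lower() in _EDGE_HEADER_TOKENS or b.lower() in _EDGE_HEADER_TOKENS):
                continue
            if a == b:
                n_self += 1
                continue
            g.add_edge(a, b)
    if n_self:
        log.info("%s: dropped %d self-loop(s)", path, n_self)
    return g


def read_lengths(path: str | Path) -> dict[str, int]:
    """Read a two-column gene/cDNA-length table into a dict (bp, > 0)."""
    path = Path(path)
    lengths: dict[str, int] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
            gene, raw = fields[0], fields[1]
            if lineno == 1 and raw.lower() in ("length", "cdna_length", "cdna_length_bp"):
                continue
            try:
                value = int(raw)
            except ValueError as exc:
                raise RowError(f"{path}:{lineno}: non-integer length {raw!r}") from exc
            if value <= 0:
                raise RowError(f"{path}:{lineno}: length must be positive, got {value}")
            lengths[gene] = value
    return lengths


def read_geneset(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a one-symbol-per-line gene list; blanks and '#' comments skipped."""
    path = Path(path)
    members = set()
    with path.open() as fh:
        for line in fh:
            sym = line.strip()
            if sym and not sym.startswith("#"):
                members.add(sym)
    return GeneSet(name or path.stem, frozenset(members))


def write_geneset(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


def write_network(
    net: nx.Graph,
    path: str | Path,
    node_path: str | Path | None = None,
    *,
    occurrence: Mapping[tuple[str, str], int] | None = None,
    node_mutation_counts: Mapping[str, int] | None = None,
    gene_sets: Sequence[GeneSet] = (),
    subgraph_ids: Mapping[str, int] | None = None,
    orphan_ids: set[int] | None = None,
) -> None:
    """Write an edge table and a companion node table (both TSV).

    Edge table columns: geneA, geneB, occurrence, subgraph_id[, orphan].
    Node table columns: gene, n_samples_mutated, one 0/1 flag per gene set.
    Subgraph labels default to connected-component indices (ordered by the
    lexicographically smallest member). Files round-trip through
    :func:`read_network`.
    """
    path = Path(path)
    if subgraph_ids is None:
        comps = sorted(nx.connected_components(net), key=lambda c: min(c))
        subgraph_ids = {g: i for i, comp in enumerate(comps) for g in comp}
    occurrence = occurrence or {}

    def _occ(a: str, b: str) -> int:
        return occurrence.get((a, b), occurrence.get((b, a), net.edges[a, b].get("occurrence", 1)))

    with path.open("w") as fh:
        cols = ["geneA", "geneB", "occurrence", "subgraph_id"]
        if orphan_ids is not None:
            cols.append("orphan")
        fh.write("\t".join(cols) + "\n")
        for a, b in sorted(net.edges(), key=lambda e: tuple(sorted(e))):
            a, b = sorted((a, b))
            row = [a, b, str(_occ(a, b)), str(subgraph_ids[a])]
            if orphan_ids is not None:
                row.append(str(int(subgraph_ids[a] in orphan_ids)))
            fh.write("\t".join(row) + "\n")

    if node_path is None:
        node_path = path.with_name(path.stem + ".nodes.tsv")
    counts = node_mutation_counts or {}
    with Path(node_path).open("w") as fh:
        cols = ["gene", "n_samples_mutated", "subgraph_id"] + [s.name for s in gene_sets]
        fh.write("\t".join(cols) + "\n")
        for g in sorted(net.nodes()):
            row = [g, str(counts.get(g, 0)), str(subgraph_ids[g])]
            row += [str(int(g in s)) for s in gene_sets]
            fh.write("\t".join(row) + "\n")
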