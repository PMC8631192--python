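"""Domain containers and readers/writers for the standard formats.

All coordinates are 0-based, half-open internally.  GFF3 is the single
exception at the file boundary (1-based, inclusive) and is converted on
read/write.  Sequences are uppercase strings over ``{A, C, G, T, N}``.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """A file or record violates the expected format."""


class Feature(NamedTuple):
    """An annotated interval on a genome (0-based, half-open)."""

    type: str
    start: int
    end: int
    strand: str
    label: str


@dataclass
class GenomeRecord:
    """A named nucleotide sequence with optional feature annotations.

    Parameters
    ----------
    id : str
        Record identifier (FASTA header word).
    seq : str
        Uppercase nucleotide sequence over ``{A, C, G, T, N}``.
    circular : bool
        Whether the molecule is circular (phage genomes sequenced in
        circular form; bacterial chromosomes).
    features : list of Feature
        Annotated intervals, e.g. tRNA loci or gene-class regions.
    """

    id: str
    seq: str
    circular: bool = False
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("genome record has an empty id")
        if not self.seq:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise FormatError(
                f"record {self.id!r}: invalid characters {sorted(bad)!r} "
                "(expected A/C/G/T/N)"
            )
        for f in self.features:
            if not (0 <= f.start < f.end <= len(self.seq)):
                raise FormatError(
                    f"record {self.id!r}: feature {f.label!r} interval "
                    f"[{f.start}, {f.end}) outside sequence of length {len(self.seq)}"
                )

    def __len__(self) -> int:
        return len(self.seq)


def _check_seq(rec_id: str, seq: str) -> str:
    seq = seq.upper()
    if not seq:
        raise FormatError(f"record {rec_id!r}: empty sequence")
    bad = set(seq) - VALID_BASES
    if bad:
        raise FormatError(
            f"record {rec_id!r}: invalid characters {sorted(bad)!r}"
        )
    return seq


def read_fasta(path) -> list[GenomeRecord]:
    """Read a (multi-)FASTA file into :class:`GenomeRecord` objects.

    Sequences are uppercased; characters outside ``{A,C,G,T,N}`` raise
    :class:`FormatError` naming the offending record.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(GenomeRecord(id=rec.id, seq=_check_seq(rec.id, str(rec.seq))))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[GenomeRecord], path) -> None:
    seqs = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3: 1-based inclusive on disk, converted to 0-based half-open in memory.
# Only the feature fields the pipeline uses are kept (type, interval, strand,
# label from the ID/Name attribute).

def read_gff3(path) -> dict[str, list[Feature]]:
    """Read a GFF3 file into ``{seqid: [Feature, ...]}``."""
    out: dict[str, list[Feature]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = cols
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            label = attr_map.get("ID") or attr_map.get("Name") or ftype
            feat = Feature(ftype, int(start) - 1, int(end), strand, label)
            out.setdefault(seqid, []).append(feat)
    return out


def write_gff3(features: dict[str, list[Feature]], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seqid, feats in features.items():
            for f in feats:
                fh.write(
                    f"{seqid}\trhizophage\t{f.type}\t{f.start + 1}\t{f.end}\t."
                    f"\t{f.strand}\t.\tID={f.label}\n"
                )


# ---------------------------------------------------------------------------
# Assay tables: long-format OD600 / PFU observations.

ASSAY_COLUMNS = [
    "series_id",
    "phage_id",
    "host_id",
    "replicate",
    "time",
    "value",
    "treatment",
]

TREATMENTS = ("phage+", "phage-")


@dataclass
class AssayTable:
    """Long-format table of plate-reader or plaque-count observations.

    One row per reading: ``(series_id, phage_id, host_id, replicate,
    time [min], value [OD600 or PFU/ml], treatment)``.  Every ``phage+``
    series is expected to have a paired ``phage-`` control under the same
    (host, replicate).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ASSAY_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"assay table missing columns {missing}")
        bad_treat = set(self.df["treatment"]) - set(TREATMENTS)
        if bad_treat:
            raise FormatError(f"unknown treatment labels {sorted(bad_treat)}")
        if (self.df["value"] < 0).any():
            raise FormatError("assay values must be >= 0")
        for sid, grp in self.df.groupby("series_id"):
            t = grp["time"].to_numpy()
            if not (t[1:] > t[:-1]).all():
                raise FormatError(
                    f"series {sid!r}: times not strictly increasing"
                )

    def series(self, series_id: str) -> pd.DataFrame:
        sub = self.df[self.df["series_id"] == series_id]
        if sub.empty:
            raise KeyError(series_id)
        return sub.sort_values("time")

    def series_ids(self) -> list[str]:
        return list(dict.fromkeys(self.df["series_id"]))

    @classmethod
    def read_csv(cls, path) -> "AssayTable":
        return cls(pd.read_csv(path))

    def write_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Rooted trees.  A deliberately small node class: the reconciliation dynamic
# program needs postorder traversal, parent links and tip labels, nothing
# more.  Newick parsing/serialisation is delegated to dendropy.


class TreeError(ValueError):
    """A tree violates a structural requirement (e.g. polytomy)."""


class TreeNode:
    """Node of a rooted tree; a tree is referenced by its root node."""

    __slots__ = ("name", "children", "parent", "length")

    def __init__(self, name: str | None = None, children=None, length=None):
        self.name = name
        self.children: list[TreeNode] = list(children or [])
        self.length = length
        self.parent: TreeNode | None = None
        for c in self.children:
            c.parent = self

    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        for c in self.children:
            yield from c.postorder()
        yield self

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf()]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def is_binary(self) -> bool:
        return all(
            len(n.children) in (0, 2) for n in self.postorder()
        )

    def copy(self) -> "TreeNode":
        return TreeNode(
            self.name, [c.copy() for c in self.children], self.length
        )

    def to_newick(self) -> str:
        def fmt(n: TreeNode) -> str:
            lab = n.name or ""
            br = "" if n.length is None else f":{n.length:g}"
            if n.is_leaf():
                return f"{lab}{br}"
            inner = ",".join(fmt(c) for c in n.children)
            return f"({inner}){lab}{br}"

        return fmt(self) + ";"

    def __repr__(self) -> str:
        return f"TreeNode({self.to_newick()!r})"


def _from_dendropy(node) -> TreeNode:
    name = node.taxon.label if node.taxon is not None else node.label
    children = [_from_dendropy(c) for c in node.child_nodes()]
    return TreeNode(name=name, children=children, length=node.edge.length)


def parse_newick(text: str, require_binary: bool = False) -> TreeNode:
    """Parse a single Newick string into a rooted :class:`TreeNode` tree."""
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=False
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"invalid Newick: {exc}") from exc
    root = _from_dendropy(dtree.seed_node)
    # dendropy may attach a unifurcating root; collapse it
    while len(root.children) == 1:
        root = root.children[0]
        root.parent = None
    if require_binary and not root.is_binary():
        raise TreeError("tree is non-binary (polytomy); reconciliation requires a binary tree")
    return root


def read_newick(path, require_binary: bool = False) -> TreeNode:
    with open(path) as fh:
        return parse_newick(fh.read(), require_binary=require_binary)


def write_newick(tree: TreeNode, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


@dataclass
class TreePair:
    """A host tree, a phage tree, and the phage-tip -> host-tip association.

    Both trees must be rooted and binary; every phage tip maps to exactly
    one existing host tip.  Host tips may be unmapped (phage-free strains).
    """

    host: TreeNode
    phage: TreeNode
    tip_map: dict[str, str]

    def __post_init__(self) -> None:
        for label, tree in (("host", self.host), ("phage", self.phage)):
            if not tree.is_binary():
                raise TreeError(f"{label} tree is non-binary")
        host_tips = set(self.host.leaf_names())
        for tip in self.phage.leaf_names():
            if tip not in self.tip_map:
                raise TreeError(f"phage tip {tip!r} has no host association")
            if self.tip_map[tip] not in host_tips:
                raise TreeError(
                    f"phage tip {tip!r} maps to unknown host tip "
                    f"{self.tip_map[tip]!r}"
                )


def read_tip_map(path) -> dict[str, str]:
    """Read a two-column CSV (phage_tip, host_tip) into a dict."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: tip map needs two columns")
    phage_col, host_col = df.columns[:2]
    if df[phage_col].duplicated().any():
        raise FormatError(f"{path}: duplicate phage tips in tip map")
    return dict(zip(df[phage_col].astype(str), df[host_col].astype(str)))


def write_tip_map(tip_map: dict[str, str], path) -> None:
    pd.DataFrame(
        {"phage_tip": list(tip_map), "host_tip": list(tip_map.values())}
    ).to_csv(path, index=False)
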