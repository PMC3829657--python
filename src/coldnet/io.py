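"""Readers, writers and in-memory containers for the pipeline's file formats.

Three containers cover everything the analysis touches:

* :class:`ExpressionMatrix` — genes x samples (or genes x conditions) of
  log2-scale expression values with optional per-sample metadata
  (ecotype, treatment, replicate).
* :class:`RegulatoryNetwork` — a directed bipartite TF -> target edge list
  with Pearson correlation, p-value and an activation/repression label.
* :class:`AlignedSequences` — pre-aligned nucleotide sequences for the
  polymorphism statistics.

On-disk formats are plain text: TSV for matrices, metadata and edge
tables, SIF and GML for network interchange, FASTA for alignments.
Expression values are kept on the log2 scale throughout; no reader or
writer exponentiates.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import (
    AlignmentError,
    FormatError,
    InputError,
    MetadataError,
    ParameterError,
    ParseError,
)

TREATMENTS = ("control", "cold")

#: Alphabet accepted in alignments: nucleotides, missing data, gaps.
ALIGNMENT_ALPHABET = frozenset("ACGTN-")

ACTIVATION = "activation"
REPRESSION = "repression"

_SIF_RELATIONS = {"activates": ACTIVATION, "represses": REPRESSION}
_SIF_TOKENS = {ACTIVATION: "activates", REPRESSION: "represses"}


def _as_handle(source: str | Path | TextIO, mode: str = "r"):
    """Return (handle, needs_close) for a path or an open text stream."""
    if isinstance(source, (str, Path)):
        return open(source, mode, encoding="utf-8"), True
    return source, False


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2 expression values.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids (or condition names,
        for condition-level fold-change matrices) as columns. All entries
        must be finite.
    metadata
        Optional per-sample DataFrame indexed by sample id with columns
        ``ecotype``, ``treatment`` (``control``/``cold``) and ``replicate``.
        Required for replicate-level data, absent for condition-level
        matrices.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dups[:5]}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups[:5]}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression values must be numeric")
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise FormatError(
                "non-finite expression value at gene "
                f"{v.index[bad[0]]!r}, sample {v.columns[bad[1]]!r}"
            )
        if self.metadata is not None:
            md = self.metadata
            missing = set(v.columns) - set(md.index)
            if missing:
                raise MetadataError(
                    f"samples missing from metadata: {sorted(missing)[:5]}"
                )
            for col in ("ecotype", "treatment", "replicate"):
                if col not in md.columns:
                    raise MetadataError(f"metadata lacks required column {col!r}")
            bad_treat = set(md["treatment"]) - set(TREATMENTS)
            if bad_treat:
                raise MetadataError(f"unknown treatment labels: {sorted(bad_treat)}")
            # keep metadata aligned with the value columns
            self.metadata = md.loc[list(v.columns)]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def ecotypes(self) -> list[str]:
        """Ecotype names in first-appearance order (replicate-level only)."""
        if self.metadata is None:
            raise MetadataError("matrix has no sample metadata")
        return list(dict.fromkeys(self.metadata["ecotype"]))

    def samples_for(self, ecotype: str, treatment: str) -> list[str]:
        """Sample ids belonging to one (ecotype, treatment) cell."""
        if self.metadata is None:
            raise MetadataError("matrix has no sample metadata")
        md = self.metadata
        mask = (md["ecotype"] == ecotype) & (md["treatment"] == treatment)
        return list(md.index[mask])


def read_expression_table(
    source: str | Path | TextIO,
    metadata_source: str | Path | TextIO | None = None,
    *,
    missing: str = "error",
) -> ExpressionMatrix:
    """Read a genes-in-rows TSV expression table (plus optional metadata).

    The first column holds gene ids, the header row sample ids. The
    metadata table maps sample id -> (ecotype, treatment, replicate).

    ``missing`` controls empty cells: ``"error"`` (default) rejects them,
    ``"impute"`` replaces them by the gene's row mean with a warning.
    """
    if missing not in ("error", "impute"):
        raise ParameterError(f"missing policy {missing!r} not in (error, impute)")
    handle, close = _as_handle(source)
    try:
        raw = pd.read_csv(handle, sep="\t", index_col=0, dtype=str)
    finally:
        if close:
            handle.close()
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna() & (raw[col].str.strip() != "")
        if bad.any():
            gene = raw.index[bad][0]
            raise ParseError(
                f"non-numeric value {raw.loc[gene, col]!r} at gene {gene!r}, "
                f"sample {col!r}"
            )
        values[col] = converted
    if values.isna().any().any():
        if missing == "error":
            gene = values.index[values.isna().any(axis=1)][0]
            raise ParseError(f"missing expression value in row {gene!r}")
        import warnings

        warnings.warn("imputing missing cells with row means", stacklevel=2)
        row_means = values.mean(axis=1)
        values = values.apply(lambda row: row.fillna(row_means[row.name]), axis=1)

    metadata = None
    if metadata_source is not None:
        mh, close = _as_handle(metadata_source)
        try:
            metadata = pd.read_csv(mh, sep="\t")
        finally:
            if close:
                mh.close()
        if "sample" not in metadata.columns:
            raise MetadataError("metadata table lacks a 'sample' column")
        if metadata["sample"].duplicated().any():
            raise MetadataError("duplicate sample rows in metadata")
        metadata = metadata.set_index("sample")
    return ExpressionMatrix(values=values, metadata=metadata)


def write_expression_table(
    em: ExpressionMatrix,
    dest: str | Path | TextIO,
    metadata_dest: str | Path | TextIO | None = None,
) -> None:
    """Write an :class:`ExpressionMatrix` (and optionally its metadata) as TSV."""
    handle, close = _as_handle(dest, "w")
    try:
        em.values.to_csv(handle, sep="\t", index_label="gene", lineterminator="\n")
    finally:
        if close:
            handle.close()
    if metadata_dest is not None:
        if em.metadata is None:
            raise MetadataError("matrix has no metadata to write")
        mh, close = _as_handle(metadata_dest, "w")
        try:
            em.metadata.to_csv(mh, sep="\t", index_label="sample", lineterminator="\n")
        finally:
            if close:
                mh.close()


# ---------------------------------------------------------------------------
# Regulatory networks
# ---------------------------------------------------------------------------


def sign_label(r: float) -> str:
    """Activation for positive correlation, repression for negative."""
    return ACTIVATION if r > 0 else REPRESSION


@dataclass
class RegulatoryNetwork:
    """Directed bipartite TF -> target edge list.

    ``edges`` columns: ``tf``, ``target``, ``r`` (Pearson correlation, may
    be NaN for sign-only sources), ``p`` (may be NaN) and ``sign``
    (``activation``/``repression``). The sign is activation iff r > 0
    whenever r is present.
    """

    edges: pd.DataFrame
    load_report: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        e = self.edges.reset_index(drop=True)
        for col in ("tf", "target", "sign"):
            if col not in e.columns:
                raise FormatError(f"edge table lacks column {col!r}")
        for col in ("r", "p"):
            if col not in e.columns:
                e[col] = np.nan
        e = e[["tf", "target", "r", "p", "sign"]].copy()
        e["tf"] = e["tf"].astype(str)
        e["target"] = e["target"].astype(str)
        e["r"] = e["r"].astype(float)
        e["p"] = e["p"].astype(float)
        if e.duplicated(subset=["tf", "target"]).any():
            pair = e.loc[e.duplicated(subset=["tf", "target"]), ["tf", "target"]]
            raise FormatError(
                f"duplicate edge {tuple(pair.iloc[0])}; merge before constructing"
            )
        with np.errstate(invalid="ignore"):
            out_of_range = (e["r"].abs() > 1) & e["r"].notna()
        if out_of_range.any():
            raise FormatError(
                f"correlation outside [-1, 1]: r={e.loc[out_of_range, 'r'].iloc[0]}"
            )
        bad_sign = ~e["sign"].isin((ACTIVATION, REPRESSION))
        if bad_sign.any():
            raise FormatError(f"unknown sign label {e.loc[bad_sign, 'sign'].iloc[0]!r}")
        has_r = e["r"].notna()
        expected = e.loc[has_r, "r"].map(sign_label)
        if (expected != e.loc[has_r, "sign"]).any():
            i = expected.index[(expected != e.loc[has_r, "sign"])][0]
            raise FormatError(
                f"sign {e.loc[i, 'sign']!r} inconsistent with r={e.loc[i, 'r']} "
                f"for edge ({e.loc[i, 'tf']}, {e.loc[i, 'target']})"
            )
        self.edges = e

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def tfs(self) -> list[str]:
        return sorted(self.edges["tf"].unique())

    @property
    def targets(self) -> list[str]:
        return sorted(self.edges["target"].unique())

    @property
    def nodes(self) -> list[str]:
        return sorted(set(self.edges["tf"]) | set(self.edges["target"]))

    @property
    def n_activations(self) -> int:
        return int((self.edges["sign"] == ACTIVATION).sum())

    @property
    def n_repressions(self) -> int:
        return int((self.edges["sign"] == REPRESSION).sum())

    def sorted_edges(self) -> pd.DataFrame:
        return self.edges.sort_values(["tf", "target"], kind="mergesort").reset_index(
            drop=True
        )

    def equals(self, other: "RegulatoryNetwork", *, values: bool = True) -> bool:
        """Structural equality; ``values=False`` compares (tf, target, sign) only."""
        a, b = self.sorted_edges(), other.sorted_edges()
        if len(a) != len(b):
            return False
        keys = ["tf", "target", "sign"]
        if not a[keys].equals(b[keys]):
            return False
        if not values:
            return True
        for col in ("r", "p"):
            av, bv = a[col].to_numpy(), b[col].to_numpy()
            both_nan = np.isnan(av) & np.isnan(bv)
            if not np.all(both_nan | np.isclose(av, bv, rtol=0, atol=1e-12)):
                return False
        return True


def _merge_duplicate_edges(e: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Keep, for each (tf, target), the record with the largest |r|."""
    n_dups = int(e.duplicated(subset=["tf", "target"]).sum())
    if n_dups == 0:
        return e, 0
    order = e["r"].abs().fillna(-1.0)
    e = e.assign(_absr=order)
    e = e.sort_values("_absr", ascending=False, kind="mergesort")
    e = e.drop_duplicates(subset=["tf", "target"], keep="first")
    e = e.drop(columns="_absr").sort_index().reset_index(drop=True)
    return e, n_dups


def read_network_table(
    source: str | Path | TextIO, dialect: str = "edge_tsv"
) -> RegulatoryNetwork:
    """Read a network edge table.

    Dialects: ``edge_tsv`` (columns tf, target, r[, p][, sign]), ``sif``
    (whitespace-delimited ``tf relation target`` with relation ``activates``
    or ``represses``) and ``gml``. Duplicate (tf, target) rows are merged
    keeping the max-|r| record; the count lands in ``load_report``.
    """
    if dialect == "edge_tsv":
        handle, close = _as_handle(source)
        try:
            e = pd.read_csv(handle, sep="\t")
        finally:
            if close:
                handle.close()
        for col in ("tf", "target"):
            if col not in e.columns:
                raise ParseError(f"edge table lacks column {col!r}")
        if "r" not in e.columns and "sign" not in e.columns:
            raise ParseError("edge table has neither an 'r' nor a 'sign' column")
        if "r" in e.columns:
            r = pd.to_numeric(e["r"], errors="coerce")
            bad = r.isna() & e["r"].notna()
            if bad.any():
                raise ParseError(f"non-numeric r value {e.loc[bad, 'r'].iloc[0]!r}")
            if ((r.abs() > 1) & r.notna()).any():
                raise ParseError("correlation outside [-1, 1]")
            e["r"] = r
        else:
            e["r"] = np.nan
        if "p" in e.columns:
            e["p"] = pd.to_numeric(e["p"], errors="coerce")
        else:
            e["p"] = np.nan
        has_r = e["r"].notna()
        if "sign" not in e.columns:
            e["sign"] = None
        e.loc[has_r, "sign"] = e.loc[has_r, "r"].map(sign_label)
        if e["sign"].isna().any():
            row = e.index[e["sign"].isna()][0]
            raise ParseError(f"row {row} has neither r nor a sign/relation")
    elif dialect == "sif":
        handle, close = _as_handle(source)
        try:
            rows = []
            for ln, line in enumerate(handle, start=1):
                line = line.strip()
                if not line:
                    continue
                parts = line.split()
                if len(parts) != 3:
                    raise ParseError(f"SIF line {ln} is not a triplet: {line!r}")
                tf, relation, target = parts
                if relation not in _SIF_RELATIONS:
                    raise ParseError(
                        f"SIF line {ln}: unknown relation {relation!r} "
                        "(expected activates/represses)"
                    )
                rows.append((tf, target, np.nan, np.nan, _SIF_RELATIONS[relation]))
        finally:
            if close:
                handle.close()
        e = pd.DataFrame(rows, columns=["tf", "target", "r", "p", "sign"])
    elif dialect == "gml":
        handle, close = _as_handle(source)
        try:
            g = nx.parse_gml(handle.read())
        finally:
            if close:
                handle.close()
        rows = []
        for tf, target, data in g.edges(data=True):
            rows.append(
                (
                    tf,
                    target,
                    float(data.get("r", math.nan)),
                    float(data.get("p", math.nan)),
                    data.get("sign"),
                )
            )
        e = pd.DataFrame(rows, columns=["tf", "target", "r", "p", "sign"])
        if e["sign"].isna().any():
            raise ParseError("GML edge without a sign attribute")
    else:
        raise ParameterError(f"unknown dialect {dialect!r}")

    e, n_dups = _merge_duplicate_edges(e)
    net = RegulatoryNetwork(edges=e)
    net.load_report = {"n_edges": len(e), "duplicates_merged": n_dups}
    return net


def write_network(
    net: RegulatoryNetwork,
    dest: str | Path | TextIO | None = None,
    dialect: str = "edge_tsv",
) -> str:
    """Serialize a network; returns the text (and writes it when dest given).

    Output edge order is deterministic: lexicographic by (tf, target).
    ``sif`` keeps only the sign; ``edge_tsv`` and ``gml`` are lossless.
    """
    e = net.sorted_edges()
    if dialect == "edge_tsv":
        buf = _io.StringIO()
        e.to_csv(buf, sep="\t", index=False, lineterminator="\n")
        text = buf.getvalue()
    elif dialect == "sif":
        lines = [
            f"{row.tf} {_SIF_TOKENS[row.sign]} {row.target}"
            for row in e.itertuples(index=False)
        ]
        text = "\n".join(lines) + ("\n" if lines else "")
    elif dialect == "gml":
        g = nx.DiGraph()
        for row in e.itertuples(index=False):
            attrs = {"sign": row.sign}
            if not math.isnan(row.r):
                attrs["r"] = float(row.r)
            if not math.isnan(row.p):
                attrs["p"] = float(row.p)
            g.add_edge(row.tf, row.target, **attrs)
        text = "\n".join(nx.generate_gml(g)) + "\n"
    else:
        raise ParameterError(f"unknown dialect {dialect!r}")
    if dest is not None:
        handle, close = _as_handle(dest, "w")
        try:
            handle.write(text)
        finally:
            if close:
                handle.close()
    return text


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------


@dataclass
class AlignedSequences:
    """n >= 2 equal-length nucleotide sequences over {A, C, G, T, N, -}."""

    seq_ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.seq_ids) != len(self.sequences):
            raise AlignmentError("seq_ids and sequences differ in length")
        if len(self.sequences) < 2:
            raise InputError("an alignment needs at least 2 sequences")
        if len(set(self.seq_ids)) != len(self.seq_ids):
            raise FormatError("duplicate sequence ids")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        for sid, seq in zip(self.seq_ids, self.sequences):
            bad = set(seq) - ALIGNMENT_ALPHABET
            if bad:
                raise ParseError(
                    f"sequence {sid!r} contains symbols outside the alphabet: "
                    f"{sorted(bad)}"
                )

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def to_array(self) -> np.ndarray:
        """(n, length) array of single characters."""
        return np.array([list(s) for s in self.sequences], dtype="<U1")

    @classmethod
    def from_array(
        cls, seq_ids: Sequence[str], arr: np.ndarray
    ) -> "AlignedSequences":
        return cls(list(seq_ids), ["".join(row) for row in arr])


def read_fasta_alignment(source: str | Path | TextIO) -> AlignedSequences:
    """Read a pre-aligned FASTA file; case is normalized to upper."""
    handle, close = _as_handle(source)
    try:
        records = list(SeqIO.parse(handle, "fasta"))
    finally:
        if close:
            handle.close()
    if len(records) < 2:
        raise InputError(f"alignment has {len(records)} record(s); need >= 2")
    ids = [rec.id for rec in records]
    seqs = [str(rec.seq).upper() for rec in records]
    return AlignedSequences(seq_ids=ids, sequences=seqs)


def write_fasta_alignment(
    aln: AlignedSequences, dest: str | Path | TextIO, width: int = 70
) -> None:
    """Write an alignment as wrapped FASTA."""
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in zip(aln.seq_ids, aln.sequences)
    ]
    handle, close = _as_handle(dest, "w")
    try:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)
    finally:
        if close:
            handle.close()
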