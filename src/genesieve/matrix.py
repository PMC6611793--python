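"""Expression matrices, sample labels and gene sets: containers and text I/O.

The on-disk formats are the plain-text dialects used throughout bulk
transcriptomics: tab-separated genes x samples tables (optionally the GCT 1.2
dialect with its ``#1.2`` version header), two-column sample/label TSVs, and
MSigDB-style GMT gene-set collections.  Matrices are always held internally as
genes x samples regardless of file orientation.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_ENSEMBL_VERSION = re.compile(r"\.\d+$")

TRANSFORM_STATES = ("raw", "log2p1", "log2p1_zscored")


class GemFormatError(ValueError):
    """Malformed expression-matrix, label or GMT file."""


class GemValidationError(ValueError):
    """Structurally valid file whose content violates an invariant."""


class GeneResolutionError(ValueError):
    """A gene set shares no identifiers with the expression matrix."""


def normalize_gene_id(gene_id: str) -> str:
    """Casefold and strip a trailing Ensembl version suffix (``.N``)."""
    return _ENSEMBL_VERSION.sub("", gene_id.strip()).casefold()


@dataclass
class ExpressionMatrix:
    """A genes x samples abundance matrix (FPKM/RPKM/TPM or log-transformed).

    Parameters
    ----------
    gene_ids, sample_ids
        Unique row / column identifiers, in matrix order.
    values
        Float matrix of shape ``(len(gene_ids), len(sample_ids))``.
    transform_state
        One of ``raw``, ``log2p1``, ``log2p1_zscored``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    transform_state: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise GemValidationError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise GemValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.transform_state not in TRANSFORM_STATES:
            raise GemValidationError(
                f"unknown transform_state {self.transform_state!r}"
            )
        seen: dict[str, str] = {}
        for g in self.gene_ids:
            key = normalize_gene_id(g)
            if key in seen:
                raise GemValidationError(
                    f"duplicate gene id {g!r} (collides with {seen[key]!r} "
                    "after identifier normalization)"
                )
            seen[key] = g
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise GemValidationError("duplicate sample ids")
        if np.isnan(self.values).any():
            i, j = np.argwhere(np.isnan(self.values))[0]
            raise GemValidationError(
                f"missing value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        self._row_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._norm_index = {normalize_gene_id(g): g for g in self.gene_ids}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def rows(self, genes: list[str]) -> np.ndarray:
        """Row indices of ``genes`` (exact identifiers)."""
        try:
            return np.array([self._row_index[g] for g in genes], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} not in matrix") from None

    def submatrix(self, genes: list[str]) -> np.ndarray:
        return self.values[self.rows(genes)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.sample_ids
        )


@dataclass
class SampleLabels:
    """Per-sample categorical class labels.

    ``class_names`` keeps first-appearance order and defines the integer
    encoding used by classifiers.
    """

    mapping: dict[str, str]
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.class_names:
            seen: list[str] = []
            for lab in self.mapping.values():
                if lab not in seen:
                    seen.append(lab)
            self.class_names = seen
        self._class_index = {c: i for i, c in enumerate(self.class_names)}

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def encode(self, sample_ids: list[str]) -> np.ndarray:
        """Integer class codes for ``sample_ids``, in the given order."""
        try:
            return np.array(
                [self._class_index[self.mapping[s]] for s in sample_ids],
                dtype=np.intp,
            )
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} has no label") from None

    def class_sizes(self) -> dict[str, int]:
        sizes = {c: 0 for c in self.class_names}
        for lab in self.mapping.values():
            sizes[lab] += 1
        return sizes


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered collection of unique gene identifiers."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        if len(self.genes) < 1:
            raise GemValidationError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise GemValidationError(f"gene set {self.name!r} has duplicates")

    @property
    def n(self) -> int:
        return len(self.genes)


def read_gem(path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read an expression matrix from a TSV or GCT 1.2 file.

    The TSV dialect has a header row of sample ids and gene ids in the first
    column.  The GCT dialect prepends a ``#1.2`` version line and a
    ``rows<TAB>cols`` dimension line, and carries a ``Description`` column
    that is discarded.
    """
    if dialect not in ("tsv", "gct"):
        raise ValueError(f"unknown dialect {dialect!r}")
    skiprows = 0
    if dialect == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            dims = fh.readline().split()
        if version != "#1.2":
            raise GemFormatError(f"GCT file must start with '#1.2', got {version!r}")
        if len(dims) != 2 or not all(d.isdigit() for d in dims):
            raise GemFormatError("GCT dimension line must be 'rows<TAB>cols'")
        skiprows = 2
    try:
        raw = pd.read_csv(path, sep="\t", skiprows=skiprows, index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise GemFormatError(f"cannot parse {path}: {exc}") from exc
    if raw.shape[1] == 0:
        raise GemFormatError(f"{path}: no sample columns found")
    if dialect == "gct":
        if raw.columns[0].casefold() != "description":
            raise GemFormatError(
                "GCT header must be Name<TAB>Description<TAB>samples..."
            )
        raw = raw.drop(columns=raw.columns[0])
        n_rows, n_cols = int(dims[0]), int(dims[1])
        if raw.shape != (n_rows, n_cols):
            raise GemFormatError(
                f"GCT dimension line says {n_rows}x{n_cols} but table is "
                f"{raw.shape[0]}x{raw.shape[1]}"
            )
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & raw.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise GemFormatError(
            f"non-numeric value {raw.iat[i, j]!r} at gene {raw.index[i]!r}, "
            f"sample {raw.columns[j]!r}"
        )
    gene_ids = [str(g) for g in raw.index]
    dup = pd.Index(gene_ids)[pd.Index(gene_ids).duplicated()]
    if len(dup):
        raise GemValidationError(f"duplicate gene id {dup[0]!r} in {path}")
    return ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=[str(s) for s in raw.columns],
        values=values.to_numpy(dtype=np.float64),
        transform_state="raw",
    )


def write_gem(gem: ExpressionMatrix, path) -> None:
    """Write the TSV dialect at full float precision (round-trip safe)."""
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(gem.sample_ids) + "\n")
        for g, row in zip(gem.gene_ids, gem.values):
            fh.write(g + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_labels(path) -> SampleLabels:
    """Read a two-column sample/label TSV, with or without a header row."""
    mapping: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise GemFormatError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, "
                    f"got {len(fields)}"
                )
            sample, label = fields[0].strip(), fields[1].strip()
            if lineno == 1 and (sample.casefold(), label.casefold()) == (
                "sample",
                "label",
            ):
                continue  # header row
            if sample in mapping:
                if mapping[sample] != label:
                    raise GemValidationError(
                        f"{path}:{lineno}: sample {sample!r} listed with "
                        f"conflicting labels {mapping[sample]!r} and {label!r}"
                    )
                continue
            mapping[sample] = label
            if label not in order:
                order.append(label)
    labels = SampleLabels(mapping=mapping, class_names=order)
    if labels.n_classes >= 2:
        small = {c: s for c, s in labels.class_sizes().items() if s < 4}
        if small:
            warnings.warn(
                f"classes with fewer than 4 samples (too small for a 70/30 "
                f"split): {small}",
                stacklevel=2,
            )
    return labels


def read_gmt(path) -> list[GeneSet]:
    """Read a GMT gene-set collection (name, description, genes per line)."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GemFormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated "
                    f"fields (name, description, genes), got {len(fields)}"
                )
            name = fields[0]
            genes: list[str] = []
            seen = set()
            for g in fields[2:]:
                g = g.strip()
                if not g:
                    continue
                if g in seen:
                    warnings.warn(
                        f"{path}:{lineno}: duplicate gene {g!r} in set "
                        f"{name!r}; keeping first occurrence",
                        stacklevel=2,
                    )
                    continue
                seen.add(g)
                genes.append(g)
            sets.append(GeneSet(name=name, genes=tuple(genes)))
    return sets


def resolve_gene_set(gs: GeneSet, gem: ExpressionMatrix) -> GeneSet:
    """Intersect a gene set with the matrix's genes.

    Matching is case-insensitive and ignores Ensembl version suffixes; the
    returned set uses the matrix's identifiers, preserving the set's order.
    Missing genes are dropped with a log message; an empty intersection is an
    error.  Idempotent: resolving a resolved set returns it unchanged.
    """
    resolved: list[str] = []
    dropped: list[str] = []
    seen = set()
    for g in gs.genes:
        hit = gem._norm_index.get(normalize_gene_id(g))
        if hit is None:
            dropped.append(g)
        elif hit not in seen:
            seen.add(hit)
            resolved.append(hit)
    if not resolved:
        raise GeneResolutionError(
            f"gene set {gs.name!r}: none of its {gs.n} genes are in the matrix"
        )
    if dropped:
        logger.info(
            "gene set %r: dropped %d/%d genes absent from the matrix: %s",
            gs.name, len(dropped), gs.n, ", ".join(dropped),
        )
    return GeneSet(name=gs.name, genes=tuple(resolved))


def preprocess(gem: ExpressionMatrix, transform: str = "log2p1") -> ExpressionMatrix:
    """Apply the configured abundance transform to a raw matrix.

    ``log2p1`` maps x -> log2(x + 1) elementwise (monotone, 0 -> 0), the
    standard variance-stabilizing choice for heavy-tailed FPKM/RPKM/TPM
    values.  Per-gene standardization is deliberately *not* done here: it is
    fitted on training partitions only, inside evaluation, to avoid leakage.
    """
    if gem.transform_state != "raw":
        raise GemValidationError(
            f"preprocess expects a raw matrix, got {gem.transform_state!r}"
        )
    if transform == "none":
        return replace(gem, values=gem.values.copy())
    if transform != "log2p1":
        raise ValueError(f"unknown transform {transform!r}")
    if (gem.values < 0).any():
        i, j = np.argwhere(gem.values < 0)[0]
        raise GemValidationError(
            f"negative abundance at gene {gem.gene_ids[i]!r}, sample "
            f"{gem.sample_ids[j]!r}: log2(x+1) undefined"
        )
    return replace(gem, values=np.log2(gem.values + 1.0), transform_state="log2p1")
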