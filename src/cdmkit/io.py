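"""Readers, writers and validated containers for the pipeline's inputs.

All inputs are plain text: tab-delimited expression matrices and sample
metadata, GMT gene sets, 2-3 column edge lists and a tab-delimited
gene-document literature corpus.  Readers tolerate CRLF line endings and
``#`` comment lines.  Intensities are already-summarised probe-level
signals in linear arbitrary units; no array-level preprocessing happens
here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

CONDITIONS = ("control", "disease")

#: Probes missing in more than this fraction of samples are dropped.
MAX_MISSING_FRACTION = 0.20


class ParseError(ValueError):
    """Malformed input file (names the offending line/cell)."""


class ValidationError(ValueError):
    """Structurally parsable input that violates a dataset invariant."""


def normalize_symbol(symbol: str) -> str:
    """Canonical gene-symbol form: stripped, uppercased.

    Idempotent; alias resolution is deliberately *not* attempted — alias
    mapping is the caller's job via the probe annotation file.
    """
    return str(symbol).strip().upper()


@dataclass
class ExpressionDataset:
    """One platform's probe x sample intensity matrix with sample labels.

    Parameters
    ----------
    platform_id : str
        Platform label (e.g. an array design accession).
    intensities : pandas.DataFrame
        Probes (rows) x samples (columns), linear arbitrary units.
        ``NaN`` marks an explicitly missing value.
    condition : pandas.Series
        Per-sample label, ``control`` or ``disease``, indexed by sample id.
    subset : pandas.Series
        Per-sample tissue-region / split label, indexed by sample id.
    """

    platform_id: str
    intensities: pd.DataFrame
    condition: pd.Series
    subset: pd.Series

    def __post_init__(self) -> None:
        samples = list(self.intensities.columns)
        for name, series in (("condition", self.condition), ("subset", self.subset)):
            missing = [s for s in samples if s not in series.index]
            if missing:
                raise ValidationError(
                    f"{self.platform_id}: samples missing a {name} label: {missing[:5]}"
                )
        bad = set(self.condition.loc[samples]) - set(CONDITIONS)
        if bad:
            raise ValidationError(
                f"{self.platform_id}: unknown condition label(s) {sorted(bad)}; "
                f"expected one of {CONDITIONS}"
            )
        vals = self.intensities.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.isinf(vals).any():
                raise ValidationError(f"{self.platform_id}: non-finite intensity values")
        if (np.nan_to_num(vals, nan=0.0) < 0).any():
            raise ValidationError(f"{self.platform_id}: negative intensity values")
        # Probes with too much missingness carry no testable signal: drop them.
        frac_missing = self.intensities.isna().mean(axis=1)
        drop = frac_missing[frac_missing > MAX_MISSING_FRACTION].index
        if len(drop):
            log.warning(
                "%s: dropping %d probes with >%.0f%% missing values",
                self.platform_id, len(drop), 100 * MAX_MISSING_FRACTION,
            )
            self.intensities = self.intensities.drop(index=drop)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_probes(self) -> int:
        return len(self.intensities.index)

    def samples_where(self, condition: str, subset: str | None = None) -> list[str]:
        """Sample ids matching a condition (and optionally a subset)."""
        mask = self.condition.loc[self.sample_ids] == condition
        if subset is not None:
            mask &= self.subset.loc[self.sample_ids] == subset
        return [s for s, m in mask.items() if m]


@dataclass
class GeneSetCollection:
    """Named gene sets (functional categories), symbols normalised."""

    sets: dict[str, set[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, term_id: str) -> set[str]:
        return self.sets[term_id]

    def items(self):
        return self.sets.items()


def _read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str,
                       keep_default_na=False, **kwargs)


def read_expression_matrix(path, metadata_path, platform_id: str | None = None) -> ExpressionDataset:
    """Read a probe x sample TSV plus its sample metadata table.

    The matrix has probe ids in the first column and sample ids in the
    header; the metadata file maps ``sample_id`` to ``condition`` and
    ``subset`` (and optionally ``platform``).  Every matrix sample must be
    present in the metadata.
    """
    raw = _read_table(path)
    if raw.shape[1] < 2:
        raise ParseError(f"{path}: expression matrix needs >=2 columns")
    probe_col = raw.columns[0]
    probes = raw[probe_col].map(str.strip)
    dup = probes[probes.duplicated()]
    if len(dup):
        raise ParseError(f"{path}: duplicate probe id {dup.iloc[0]!r}")
    values = {}
    for col in raw.columns[1:]:
        cleaned = raw[col].str.strip().replace({"": None, "NA": None, "nan": None})
        converted = pd.to_numeric(cleaned, errors="coerce")
        bad = converted.isna() & cleaned.notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ParseError(
                f"{path}: non-numeric value {cleaned.iloc[row]!r} at "
                f"probe {probes.iloc[row]!r}, sample column {col!r}"
            )
        values[col] = converted.to_numpy(dtype=float)
    mat = pd.DataFrame(values, index=pd.Index(probes, name="probe_id"))

    meta = _read_table(metadata_path)
    required = {"sample_id", "condition", "subset"}
    if not required.issubset(meta.columns):
        raise ParseError(f"{metadata_path}: metadata needs columns {sorted(required)}")
    meta = meta.set_index("sample_id")
    absent = [s for s in mat.columns if s not in meta.index]
    if absent:
        raise ValidationError(
            f"{path}: sample(s) missing from metadata {metadata_path}: {absent}"
        )
    if platform_id is None:
        platform_id = str(meta["platform"].iloc[0]) if "platform" in meta.columns else "unknown"
    return ExpressionDataset(
        platform_id=platform_id,
        intensities=mat,
        condition=meta["condition"].map(str.strip),
        subset=meta["subset"].map(str.strip),
    )


def write_expression_matrix(dataset: ExpressionDataset, path, metadata_path) -> None:
    """Write a dataset back to the canonical TSV pair (round-trips)."""
    out = dataset.intensities.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", na_rep="NA")
    meta = pd.DataFrame({
        "sample_id": dataset.sample_ids,
        "condition": dataset.condition.loc[dataset.sample_ids].to_numpy(),
        "subset": dataset.subset.loc[dataset.sample_ids].to_numpy(),
        "platform": dataset.platform_id,
    })
    meta.to_csv(metadata_path, sep="\t", index=False)


def read_probe_annotation(path) -> pd.DataFrame:
    """Read probe -> gene symbol mapping: columns probe_id, gene_symbol[, platform].

    Each probe maps to at most one symbol; symbols are normalised and empty
    mappings dropped.
    """
    tab = _read_table(path)
    if not {"probe_id", "gene_symbol"}.issubset(tab.columns):
        raise ParseError(f"{path}: annotation needs columns probe_id, gene_symbol")
    tab["probe_id"] = tab["probe_id"].map(str.strip)
    tab["gene_symbol"] = tab["gene_symbol"].map(normalize_symbol)
    tab = tab[tab["gene_symbol"] != ""]
    dup = tab["probe_id"][tab["probe_id"].duplicated()]
    if len(dup):
        raise ParseError(f"{path}: probe {dup.iloc[0]!r} annotated more than once")
    return tab.reset_index(drop=True)


def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file: ``term_id <TAB> description <TAB> member...``.

    Members are symbol-normalised; terms left empty after normalisation are
    dropped with a warning; a duplicated term id is an error.
    """
    sets: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: GMT line needs >=2 tab-separated fields")
            term_id = fields[0].strip()
            if term_id in sets:
                raise ParseError(f"{path}:{lineno}: duplicate term id {term_id!r}")
            members = {normalize_symbol(m) for m in fields[2:] if m.strip()}
            if not members:
                warnings.warn(f"{path}:{lineno}: term {term_id!r} has no members; dropped")
                continue
            sets[term_id] = members
            names[term_id] = fields[1].strip()
    return GeneSetCollection(sets=sets, names=names)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for term_id in sorted(collection.sets):
            members = sorted(collection.sets[term_id])
            name = collection.names.get(term_id, term_id)
            fh.write("\t".join([term_id, name, *members]) + "\n")


def read_edge_list(path, keep_isolated: bool = False):
    """Read an undirected interaction edge list (2-3 tab-separated columns).

    Self-loops are removed, duplicate and reversed duplicate edges
    collapsed, node symbols normalised.  With ``keep_isolated``, nodes whose
    only edges were self-loops are retained as isolated nodes.
    """
    import networkx as nx

    graph = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: edge line needs >=2 columns")
            a, b = normalize_symbol(fields[0]), normalize_symbol(fields[1])
            if a == b:
                if keep_isolated:
                    graph.add_node(a)
                continue
            graph.add_edge(a, b)
    return graph


def write_edge_list(graph, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{a}\t{b}\n")


def read_corpus(path) -> pd.DataFrame:
    """Read the offline literature corpus.

    Tab-delimited: ``document_id <TAB> gene;gene;... <TAB> tag;tag;...``.
    Returns a frame with columns ``document_id``, ``genes`` (frozenset of
    normalised symbols) and ``tags`` (frozenset of lower-case labels).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: corpus line needs 3 columns")
            genes = frozenset(normalize_symbol(g) for g in fields[1].split(";") if g.strip())
            tags = frozenset(t.strip().lower() for t in fields[2].split(";") if t.strip())
            rows.append((fields[0].strip(), genes, tags))
    if not rows:
        raise ValidationError(f"{path}: corpus is empty")
    return pd.DataFrame(rows, columns=["document_id", "genes", "tags"])


def write_corpus(corpus: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for _, row in corpus.iterrows():
            fh.write("\t".join([
                row["document_id"],
                ";".join(sorted(row["genes"])),
                ";".join(sorted(row["tags"])),
            ]) + "\n")
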