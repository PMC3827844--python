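"""Literature semantic-tag enrichment against an offline corpus.

Emulates the validation step in which each tier's gene list is turned
into a Boolean OR query, crossed with delimiting topic expressions
(disease, cancer, stress, disease-specific terms), and the ratio of
delimited to undelimited hit counts is compared between tiers and a
size-matched random gene control.  The corpus is a local gene-document
table (see :func:`cdmkit.io.read_corpus`); a networked literature backend
can be plugged in by implementing the same ``count_hits`` contract.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import normalize_symbol

DEFAULT_N_CONTROL_RESAMPLES = 50


# --- Boolean tag expressions -------------------------------------------------

_TOKEN = re.compile(r"\s*(\(|\)|\w[\w\-]*)")


class ExpressionParseError(ValueError):
    """Malformed Boolean tag expression."""


def _tokenize(text: str) -> list[str]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            if text[pos:].strip():
                raise ExpressionParseError(f"bad character at {text[pos:]!r}")
            break
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive-descent parser for ``tag``, AND, OR, NOT and parentheses."""

    def __init__(self, text: str):
        self.tokens = _tokenize(text)
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse(self):
        node = self.parse_or()
        if self.peek() is not None:
            raise ExpressionParseError(f"unexpected token {self.peek()!r}")
        return node

    def parse_or(self):
        node = self.parse_and()
        while self.peek() is not None and self.peek().lower() == "or":
            self.take()
            rhs = self.parse_and()
            node = ("or", node, rhs)
        return node

    def parse_and(self):
        node = self.parse_not()
        while self.peek() is not None and self.peek().lower() == "and":
            self.take()
            rhs = self.parse_not()
            node = ("and", node, rhs)
        return node

    def parse_not(self):
        tok = self.peek()
        if tok is None:
            raise ExpressionParseError("unexpected end of expression")
        if tok.lower() == "not":
            self.take()
            return ("not", self.parse_not())
        return self.parse_atom()

    def parse_atom(self):
        tok = self.take()
        if tok == "(":
            node = self.parse_or()
            if self.take() != ")":
                raise ExpressionParseError("unbalanced parentheses")
            return node
        if tok in (")", None) or tok.lower() in ("and", "or", "not"):
            raise ExpressionParseError(f"unexpected token {tok!r}")
        return ("tag", tok.lower())


def parse_delimiter(expression: str):
    """Parse a Boolean tag expression into an evaluable AST."""
    return _Parser(expression).parse()


def _eval(node, tags: frozenset) -> bool:
    op = node[0]
    if op == "tag":
        return node[1] in tags
    if op == "not":
        return not _eval(node[1], tags)
    if op == "and":
        return _eval(node[1], tags) and _eval(node[2], tags)
    return _eval(node[1], tags) or _eval(node[2], tags)


# --- hit counting and enrichment ---------------------------------------------

def count_hits(corpus: pd.DataFrame, genes, delimiter: str | None = None) -> int:
    """Documents mentioning >=1 listed gene and satisfying the delimiter.

    ``delimiter=None`` imposes no tag constraint (the "total" query of a
    Boolean-OR gene list).
    """
    gene_set = {normalize_symbol(g) for g in genes}
    if not gene_set:
        warnings.warn("count_hits called with an empty gene list")
        return 0
    ast = parse_delimiter(delimiter) if delimiter is not None else None
    n = 0
    for doc_genes, doc_tags in zip(corpus["genes"], corpus["tags"]):
        if gene_set.isdisjoint(doc_genes):
            continue
        if ast is None or _eval(ast, doc_tags):
            n += 1
    return n


def hit_ratio(corpus: pd.DataFrame, genes, delimiter: str) -> tuple[float, int, int]:
    """(delimited/total ratio, delimited hits, total hits) for a gene list."""
    total = count_hits(corpus, genes, None)
    hits = count_hits(corpus, genes, delimiter)
    ratio = hits / total if total > 0 else float("nan")
    return ratio, hits, total


def background_tag_rate(corpus: pd.DataFrame, genes, delimiter: str) -> float:
    """Delimiter rate among documents mentioning none of the listed genes.

    The complement of :func:`hit_ratio`: the baseline tag rate of the
    literature outside the query list, the unbiased reference when
    estimating how strongly a gene list is associated with a topic
    (size-matched random controls overlap cross-mentioning documents and
    therefore attenuate strong associations).
    """
    gene_set = {normalize_symbol(g) for g in genes}
    if not gene_set:
        warnings.warn("background_tag_rate called with an empty gene list")
        return float("nan")
    ast = parse_delimiter(delimiter)
    hits = total = 0
    for doc_genes, doc_tags in zip(corpus["genes"], corpus["tags"]):
        if not gene_set.isdisjoint(doc_genes):
            continue
        total += 1
        if _eval(ast, doc_tags):
            hits += 1
    return hits / total if total > 0 else float("nan")


@dataclass
class SemanticEnrichmentResult:
    list_label: str
    delimiter: str
    hits: int
    total_hits: int
    ratio: float
    fold_vs_control: float
    control_ratio: float


def control_ratio(corpus: pd.DataFrame, background_genes, list_size: int,
                  delimiter: str, n_resamples: int = DEFAULT_N_CONTROL_RESAMPLES,
                  rng: np.random.Generator | None = None, seed: int | None = None) -> float:
    """Mean delimited/total ratio over size-matched random gene samples.

    Samples are drawn without replacement from the measured background;
    resamples with zero total hits contribute nothing (flagged by NaN when
    every resample is empty).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    background = sorted({normalize_symbol(g) for g in background_genes})
    if list_size > len(background):
        raise ValueError("control list larger than background")
    ratios = []
    for _ in range(n_resamples):
        sample = rng.choice(background, size=list_size, replace=False)
        r, _, total = hit_ratio(corpus, sample, delimiter)
        if total > 0:
            ratios.append(r)
    return float(np.mean(ratios)) if ratios else float("nan")


def relative_enrichment(corpus: pd.DataFrame, genes, delimiter: str,
                        control: float, list_label: str = "") -> SemanticEnrichmentResult:
    """Fold enrichment of a list's delimited hit ratio over the control ratio."""
    ratio, hits, total = hit_ratio(corpus, genes, delimiter)
    if not np.isfinite(control) or control == 0:
        fold = float("nan")
    else:
        fold = ratio / control
    return SemanticEnrichmentResult(
        list_label=list_label, delimiter=delimiter, hits=hits,
        total_hits=total, ratio=ratio, fold_vs_control=fold,
        control_ratio=control,
    )


def subset_variance(corpus: pd.DataFrame, genes, delimiter: str, k_splits: int,
                    seed: int | None = None, rng: np.random.Generator | None = None) -> float:
    """Pooled variance of the hit ratio over k random equal splits of the list.

    The list is shuffled (seeded) and cut into ``k_splits`` near-equal
    subsets; the delimited/total ratio is computed independently for each
    and their sample variance returned — the variation is pooled and
    attributed equally to each subset.
    """
    genes = sorted({normalize_symbol(g) for g in genes})
    if k_splits < 2:
        raise ValueError("k_splits must be >= 2")
    if len(genes) < k_splits:
        raise ValueError(f"gene list of size {len(genes)} cannot make {k_splits} splits")
    if rng is None:
        rng = np.random.default_rng(seed)
    perm = rng.permutation(len(genes))
    splits = np.array_split(np.asarray(genes, dtype=object)[perm], k_splits)
    ratios = [hit_ratio(corpus, split, delimiter)[0] for split in splits]
    return float(np.var(ratios, ddof=1))


def onco_suppressor_ratio(corpus: pd.DataFrame, genes,
                          onco_tag: str = "oncogene",
                          suppressor_tag: str = "tumor_suppressor") -> float:
    """Ratio of oncogene-tagged to tumor-suppressor-tagged document hits.

    Returns ``inf`` (a flagged, not thrown, condition) when no document is
    suppressor-tagged, and NaN when neither tag hits.
    """
    onco = count_hits(corpus, genes, onco_tag)
    supp = count_hits(corpus, genes, suppressor_tag)
    if supp == 0:
        return float("nan") if onco == 0 else float("inf")
    return onco / supp
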