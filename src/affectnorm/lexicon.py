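"""Norm tables, embedding tables, scale normalization and data splits.

A *norm lexicon* holds per-word mean ratings on one or more lexical-semantic
metrics (valence, arousal, concreteness, ...), optionally with the rating SD,
the number of raters and the proportion of participants who knew the word.
An *embedding lexicon* holds one d-dimensional real vector per word.

Words are compared case-sensitively after Unicode NFC normalization.
Duplicate words are a hard error: a silent last-wins rule would corrupt
train/validation/test splits downstream.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NormLexicon",
    "EmbeddingLexicon",
    "SplitSpec",
    "LexiconError",
    "SchemaError",
    "DuplicateWordError",
    "RatingParseError",
    "ScaleRangeError",
    "EmbeddingFormatError",
    "read_norm_table",
    "write_norm_table",
    "normalize_norms",
    "split_lexicon",
    "read_embeddings",
    "write_embeddings",
    "read_split",
    "write_split",
]


class LexiconError(ValueError):
    """Base class for lexicon input errors."""


class SchemaError(LexiconError):
    """A column named in the schema mapping is absent from the file."""


class DuplicateWordError(LexiconError):
    """The same (NFC-normalized) word appears more than once."""


class RatingParseError(LexiconError):
    """A rating cell is present but not numeric."""


class ScaleRangeError(LexiconError):
    """A rating falls outside the declared rating scale."""


class EmbeddingFormatError(LexiconError):
    """An embedding file does not conform to its declared dialect."""


def _nfc(word: str) -> str:
    return unicodedata.normalize("NFC", str(word))


@dataclass(frozen=True)
class NormLexicon:
    """Words with per-metric mean ratings, optional SDs, rater counts and
    proportion-known.

    ``means`` (and ``sds`` when present) are ``(n_words, n_metrics)`` float
    arrays; a NaN entry means the word has no rating for that metric.
    ``scale`` records the rating scale the means currently live on;
    ``(0.0, 1.0)`` after normalization.
    """

    words: tuple[str, ...]
    metrics: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray | None = None
    n_raters: np.ndarray | None = None
    known_prop: np.ndarray | None = None
    scale: tuple[float, float] = (0.0, 1.0)
    _index: dict[str, int] = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if len(set(self.words)) != len(self.words):
            raise DuplicateWordError("lexicon words must be unique")
        means = np.asarray(self.means, dtype=float)
        if means.shape != (len(self.words), len(self.metrics)):
            raise LexiconError(
                f"means shape {means.shape} does not match "
                f"{len(self.words)} words x {len(self.metrics)} metrics"
            )
        object.__setattr__(self, "means", means)
        if self.sds is not None:
            sds = np.asarray(self.sds, dtype=float)
            if sds.shape != means.shape:
                raise LexiconError("sds shape must match means")
            if np.nanmin(sds, initial=0.0) < 0:
                raise LexiconError("rating SDs must be non-negative")
            object.__setattr__(self, "sds", sds)
        if self.n_raters is not None:
            n = np.asarray(self.n_raters)
            if n.shape != (len(self.words),):
                raise LexiconError("n_raters must be one value per word")
            if np.nanmin(n, initial=1) < 1:
                raise LexiconError("n_raters must be >= 1")
            object.__setattr__(self, "n_raters", n)
        if self.known_prop is not None:
            kp = np.asarray(self.known_prop, dtype=float)
            valid = kp[~np.isnan(kp)]
            if valid.size and (valid.min() < 0 or valid.max() > 1):
                raise LexiconError("known_prop must lie in [0, 1]")
            object.__setattr__(self, "known_prop", kp)
        object.__setattr__(self, "_index", {w: i for i, w in enumerate(self.words)})

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, word: str) -> bool:
        return _nfc(word) in self._index

    def index(self, word: str) -> int:
        return self._index[_nfc(word)]

    def metric_values(self, metric: str) -> np.ndarray:
        """Mean ratings for one metric, aligned with ``self.words`` (may
        contain NaN for unrated words)."""
        return self.means[:, self.metrics.index(metric)]

    def subset(self, words: Sequence[str]) -> "NormLexicon":
        """Restrict the lexicon to ``words`` (kept in the given order)."""
        idx = np.array([self.index(w) for w in words], dtype=int)
        return replace(
            self,
            words=tuple(self.words[i] for i in idx),
            means=self.means[idx],
            sds=None if self.sds is None else self.sds[idx],
            n_raters=None if self.n_raters is None else self.n_raters[idx],
            known_prop=None if self.known_prop is None else self.known_prop[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"word": list(self.words)})
        for j, m in enumerate(self.metrics):
            df[f"{m}_mean"] = self.means[:, j]
            if self.sds is not None:
                df[f"{m}_sd"] = self.sds[:, j]
        if self.n_raters is not None:
            df["n_raters"] = self.n_raters
        if self.known_prop is not None:
            df["known_prop"] = self.known_prop
        return df


@dataclass(frozen=True)
class EmbeddingLexicon:
    """A vocabulary with one d-dimensional real vector per word."""

    words: tuple[str, ...]
    vectors: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if len(set(self.words)) != len(self.words):
            raise DuplicateWordError("embedding words must be unique")
        vec = np.asarray(self.vectors, dtype=float)
        if vec.ndim != 2 or vec.shape[0] != len(self.words) or vec.shape[1] < 1:
            raise LexiconError(f"bad vector array shape {vec.shape}")
        if not np.all(np.isfinite(vec)):
            raise LexiconError("embedding vectors contain non-finite entries")
        object.__setattr__(self, "vectors", vec)
        object.__setattr__(self, "_index", {w: i for i, w in enumerate(self.words)})

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, word: str) -> bool:
        return _nfc(word) in self._index

    def index(self, word: str) -> int:
        return self._index[_nfc(word)]

    def vector(self, word: str) -> np.ndarray:
        return self.vectors[self.index(word)]

    def matrix(self, words: Sequence[str]) -> np.ndarray:
        """Stack the vectors of ``words`` into an (n, d) array."""
        return self.vectors[[self.index(w) for w in words]]


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint train/validation/test word lists plus the shuffle seed."""

    train_words: tuple[str, ...]
    val_words: tuple[str, ...]
    test_words: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        tr, va, te = set(self.train_words), set(self.val_words), set(self.test_words)
        if tr & va or tr & te or va & te:
            raise LexiconError("split parts must be pairwise disjoint")


# ---------------------------------------------------------------------------
# norm tables


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_norm_table(path: str | Path, schema: Mapping) -> NormLexicon:
    """Read a delimited norm table.

    ``schema`` maps roles to column names::

        {"word": "word",
         "means": {"valence": "valence_mean", "arousal": "arousal_mean"},
         "sds": {"valence": "valence_sd"},          # optional
         "n_raters": "n",                            # optional
         "known_prop": "known"}                      # optional

    Raises :class:`SchemaError` for a missing mapped column,
    :class:`DuplicateWordError` for repeated words and
    :class:`RatingParseError` (naming row and column) for non-numeric cells.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    word_col = schema["word"]
    mean_cols: Mapping[str, str] = schema["means"]
    if not mean_cols:
        raise SchemaError("schema must name at least one metric-mean column")
    sd_cols: Mapping[str, str] = schema.get("sds") or {}
    needed = [word_col, *mean_cols.values(), *sd_cols.values()]
    for role in ("n_raters", "known_prop"):
        if schema.get(role):
            needed.append(schema[role])
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"columns {missing} not found in {path.name}")

    words = [_nfc(w) for w in df[word_col]]
    seen: set[str] = set()
    for w in words:
        if w in seen:
            raise DuplicateWordError(f"duplicate word {w!r} in {path.name}")
        seen.add(w)

    def numeric(col: str, required: bool) -> np.ndarray:
        raw = df[col].str.strip()
        out = pd.to_numeric(raw.replace("", np.nan), errors="coerce")
        bad = out.isna() & (raw != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise RatingParseError(
                f"non-numeric value {raw.iloc[row]!r} in column {col!r}, "
                f"row {row + 2} of {path.name}"
            )
        return out.to_numpy(dtype=float)

    metrics = tuple(mean_cols)
    means = np.column_stack([numeric(mean_cols[m], True) for m in metrics])
    sds = None
    if sd_cols:
        sds = np.full_like(means, np.nan)
        for m, col in sd_cols.items():
            sds[:, metrics.index(m)] = numeric(col, False)
    n_raters = None
    if schema.get("n_raters"):
        n_raters = numeric(schema["n_raters"], False)
    known = numeric(schema["known_prop"], False) if schema.get("known_prop") else None
    lo = float(np.nanmin(means)) if np.isfinite(means).any() else 0.0
    hi = float(np.nanmax(means)) if np.isfinite(means).any() else 1.0
    # scale is whatever the file is on; caller declares it via normalize_norms
    return NormLexicon(
        words=tuple(words), metrics=metrics, means=means, sds=sds,
        n_raters=n_raters, known_prop=known,
        scale=(min(lo, 0.0), max(hi, 1.0)),
    )


def write_norm_table(lex: NormLexicon, path: str | Path) -> None:
    path = Path(path)
    lex.to_frame().to_csv(path, sep=_sep_for(path), index=False,
                          float_format="%.9g", encoding="utf-8")


def default_schema(lex: NormLexicon) -> dict:
    """The schema under which :func:`write_norm_table` output reads back."""
    schema: dict = {"word": "word", "means": {m: f"{m}_mean" for m in lex.metrics}}
    if lex.sds is not None:
        schema["sds"] = {m: f"{m}_sd" for m in lex.metrics}
    if lex.n_raters is not None:
        schema["n_raters"] = "n_raters"
    if lex.known_prop is not None:
        schema["known_prop"] = "known_prop"
    return schema


def normalize_norms(
    lex: NormLexicon, scale_min: float, scale_max: float
) -> NormLexicon:
    """Map means from the declared rating scale onto [0, 1].

    ``mean' = (mean - scale_min) / (scale_max - scale_min)``; SDs are divided
    by the scale width. Uses the *declared* endpoints, never the empirical
    min/max (see :func:`normalize_norms_empirical` for the latter).
    Normalizing an already (0, 1) lexicon with ``(0, 1)`` is the identity.
    """
    if not scale_max > scale_min:
        raise ScaleRangeError("scale_max must exceed scale_min")
    finite = lex.means[np.isfinite(lex.means)]
    if finite.size and (finite.min() < scale_min or finite.max() > scale_max):
        raise ScaleRangeError(
            f"ratings outside declared scale [{scale_min}, {scale_max}]: "
            f"observed [{finite.min()}, {finite.max()}]"
        )
    width = scale_max - scale_min
    return replace(
        lex,
        means=(lex.means - scale_min) / width,
        sds=None if lex.sds is None else lex.sds / width,
        scale=(0.0, 1.0),
    )


def normalize_norms_empirical(lex: NormLexicon) -> NormLexicon:
    """Normalize each metric by its empirical min/max (per-metric)."""
    lo = np.nanmin(lex.means, axis=0)
    hi = np.nanmax(lex.means, axis=0)
    width = hi - lo
    if np.any(width <= 0):
        raise ScaleRangeError("a metric is constant; empirical scaling undefined")
    return replace(
        lex,
        means=(lex.means - lo) / width,
        sds=None if lex.sds is None else lex.sds / width,
        scale=(0.0, 1.0),
    )


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_lexicon(
    lex: NormLexicon,
    ratios: Sequence[float],
    holdout_words: Sequence[str] = (),
    seed: int = 0,
) -> SplitSpec:
    """Partition lexicon words into train/validation(/test) sets.

    When ``holdout_words`` is given (holdout-by-exclusion), the test set is
    the intersection of the holdout list with the lexicon; those words are
    removed and the remainder is shuffled (seeded) and divided by ``ratios``
    = (train, val). Without a holdout, ``ratios`` may be (train, val) or
    (train, val, test). Validation/test sizes use round-half-up of
    N * ratio; train absorbs the remainder. Deterministic for a fixed seed.
    """
    ratios = [float(r) for r in ratios]
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise LexiconError(f"ratios must sum to 1, got {sum(ratios)}")
    holdout = {_nfc(w) for w in holdout_words}
    if holdout and len(ratios) == 3:
        raise LexiconError("give either a 3-way ratio or a holdout list, not both")
    test = tuple(w for w in lex.words if w in holdout)
    rest = [w for w in lex.words if w not in holdout]
    if not rest:
        raise LexiconError("no words left after holdout subtraction")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(rest))
    shuffled = [rest[i] for i in order]
    n = len(shuffled)
    n_val = _round_half_up(n * ratios[1])
    if len(ratios) == 3:
        n_test = _round_half_up(n * ratios[2])
        test = tuple(shuffled[n_val : n_val + n_test])
        train = tuple(shuffled[n_val + n_test :])
    else:
        train = tuple(shuffled[n_val:])
    val = tuple(shuffled[:n_val])
    return SplitSpec(train_words=train, val_words=val, test_words=test, seed=seed)


def write_split(split: SplitSpec, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("word\tsplit\n")
        for part, words in (
            ("train", split.train_words),
            ("val", split.val_words),
            ("test", split.test_words),
        ):
            for w in words:
                fh.write(f"{w}\t{part}\n")


def read_split(path: str | Path, seed: int = 0) -> SplitSpec:
    df = pd.read_csv(path, sep="\t", dtype=str)
    parts: dict[str, list[str]] = {"train": [], "val": [], "test": []}
    for w, p in zip(df["word"], df["split"]):
        if p not in parts:
            raise LexiconError(f"unknown split label {p!r}")
        parts[p].append(_nfc(w))
    return SplitSpec(
        train_words=tuple(parts["train"]),
        val_words=tuple(parts["val"]),
        test_words=tuple(parts["test"]),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# embedding tables


def read_embeddings(path: str | Path, dialect: str = "word2vec-text") -> EmbeddingLexicon:
    """Read an embedding table.

    ``word2vec-text``: first line ``"V d"``, then V lines ``word v1 ... vd``.
    ``tsv``: headerless, word followed by d tab-separated floats.
    """
    path = Path(path)
    words: list[str] = []
    rows: list[list[float]] = []
    with open(path, encoding="utf-8") as fh:
        if dialect == "word2vec-text":
            header = fh.readline().split()
            if len(header) != 2:
                raise EmbeddingFormatError(f"bad word2vec header in {path.name}")
            v_count, dim = int(header[0]), int(header[1])
            for ln, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split(" ")
                if len(parts) != dim + 1:
                    raise EmbeddingFormatError(
                        f"line {ln}: expected {dim} values, got {len(parts) - 1}"
                    )
                words.append(_nfc(parts[0]))
                rows.append([float(v) for v in parts[1:]])
            if len(words) != v_count:
                raise EmbeddingFormatError(
                    f"header promises {v_count} rows, file has {len(words)}"
                )
        elif dialect == "tsv":
            dim = None
            for ln, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if dim is None:
                    dim = len(parts) - 1
                    if dim < 1:
                        raise EmbeddingFormatError("tsv rows need word + >=1 float")
                if len(parts) != dim + 1:
                    raise EmbeddingFormatError(
                        f"line {ln}: expected {dim} values, got {len(parts) - 1}"
                    )
                words.append(_nfc(parts[0]))
                rows.append([float(v) for v in parts[1:]])
        else:
            raise LexiconError(f"unknown embedding dialect {dialect!r}")
    if not words:
        raise EmbeddingFormatError(f"no vectors in {path.name}")
    return EmbeddingLexicon(words=tuple(words), vectors=np.array(rows, dtype=float))


def write_embeddings(
    emb: EmbeddingLexicon, path: str | Path, dialect: str = "word2vec-text"
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if dialect == "word2vec-text":
            fh.write(f"{len(emb)} {emb.dim}\n")
            sep = " "
        elif dialect == "tsv":
            sep = "\t"
        else:
            raise LexiconError(f"unknown embedding dialect {dialect!r}")
        for w, vec in zip(emb.words, emb.vectors):
            fh.write(w + sep + sep.join(f"{v:.9g}" for v in vec) + "\n")
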