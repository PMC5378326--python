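"""Ingestion and aggregation of per-mutant protein-design score tables.

Each deletion mutant is represented by a set of design-model total scores
(Rosetta-style; lower = more favorable), nominally 100 per mutant.  The
predictor used downstream is the arithmetic mean of those totals.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import SchemaError

logger = logging.getLogger(__name__)

DEFAULT_EXPECTED_COUNT = 100


@dataclass
class ScoreSet:
    """Design-model total scores for one mutant."""

    mutant_id: str
    scores: np.ndarray
    expected_count: int = DEFAULT_EXPECTED_COUNT

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.size == 0:
            raise SchemaError(f"empty score set for mutant {self.mutant_id!r}")
        if not np.all(np.isfinite(self.scores)):
            raise SchemaError(
                f"non-finite scores for mutant {self.mutant_id!r}"
            )

    def __len__(self) -> int:
        return self.scores.size


def parse_score_table(
    text: str,
    score_column: str = "total_score",
    mutant_id: str = "",
    expected_count: int = DEFAULT_EXPECTED_COUNT,
) -> ScoreSet:
    """Parse one delimited score table (whitespace- or comma-separated).

    The dialect is auto-detected from the header row; the header must
    contain ``score_column`` and every entry in that column must be numeric.
    Row order is preserved.
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise SchemaError("empty score table")
    header = lines[0]
    sep = "," if "," in header else r"\s+"
    df = pd.read_csv(io.StringIO(text), sep=sep, engine="python")
    if score_column not in df.columns:
        raise SchemaError(
            f"score table lacks column {score_column!r}; "
            f"found {list(df.columns)}"
        )
    if len(df) == 0:
        raise SchemaError("score table has a header but no data rows")
    try:
        values = pd.to_numeric(df[score_column], errors="raise").to_numpy(
            dtype=float
        )
    except (ValueError, TypeError) as exc:
        raise SchemaError(
            f"non-numeric entry in column {score_column!r}: {exc}"
        ) from exc
    return ScoreSet(
        mutant_id=mutant_id, scores=values, expected_count=expected_count
    )


def mean_score(scoreset: ScoreSet) -> float:
    """Arithmetic mean of a mutant's design scores.

    Logs a warning when the number of scores differs from the nominal
    model count (100 in the standard design protocol).
    """
    if len(scoreset) != scoreset.expected_count:
        logger.warning(
            "mutant %s has %d scores (expected %d); averaging anyway",
            scoreset.mutant_id, len(scoreset), scoreset.expected_count,
        )
    return float(np.mean(scoreset.scores))


def load_score_directory(
    directory: str | Path,
    score_column: str = "total_score",
    expected_count: int = DEFAULT_EXPECTED_COUNT,
) -> dict[str, ScoreSet]:
    """Load one score file per mutant from ``directory``.

    Files are matched by the pattern ``<mutant_id>.*`` (the stem is the
    mutant id); hidden files are ignored.
    """
    directory = Path(directory)
    sets: dict[str, ScoreSet] = {}
    for path in sorted(directory.iterdir()):
        if not path.is_file() or path.name.startswith("."):
            continue
        sets[path.stem] = parse_score_table(
            path.read_text(),
            score_column=score_column,
            mutant_id=path.stem,
            expected_count=expected_count,
        )
    if not sets:
        raise SchemaError(f"no score files found in {directory}")
    return sets


def parse_long_scores(
    text: str,
    score_column: str = "total_score",
    id_column: str = "mutant_id",
    expected_count: int = DEFAULT_EXPECTED_COUNT,
) -> dict[str, ScoreSet]:
    """Parse a single long CSV holding scores for many mutants."""
    df = pd.read_csv(io.StringIO(text))
    for col in (id_column, score_column):
        if col not in df.columns:
            raise SchemaError(f"long score table lacks column {col!r}")
    sets = {}
    for mid, group in df.groupby(id_column, sort=False):
        sets[str(mid)] = ScoreSet(
            mutant_id=str(mid),
            scores=group[score_column].to_numpy(dtype=float),
            expected_count=expected_count,
        )
    return sets


def mean_scores(sets: Mapping[str, ScoreSet]) -> dict[str, float]:
    """Mean design score per mutant id."""
    return {mid: mean_score(s) for mid, s in sets.items()}
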