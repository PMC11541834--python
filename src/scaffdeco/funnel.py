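"""Multi-stage percentile-retention virtual screening funnel.

Candidates carry per-stage scores in kcal/mol with the docking convention
that lower is better.  Each stage rescоres the survivors with its scorer and
keeps the top ⌈fraction·N⌉; ties break by score then id, so results are
independent of input order.  A final threshold filter (e.g. an MM-GBSA
affinity cutoff) and a ranking table round out the triage.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import pandas as pd


class FunnelError(ValueError):
    pass


@dataclass(frozen=True)
class ScoredRecord:
    """A candidate with per-stage scores (kcal/mol, lower = better) and an
    optional affinity (e.g. MM-GBSA ΔG)."""

    id: str
    smiles: str | None = None
    scores: dict = field(default_factory=dict)
    affinity: float | None = None
    mw: float | None = None

    def score(self, stage: str) -> float:
        try:
            value = self.scores[stage]
        except KeyError:
            raise FunnelError(f"record {self.id!r} has no score for stage {stage!r}")
        if not math.isfinite(value):
            raise FunnelError(f"record {self.id!r} has non-finite score for stage {stage!r}")
        return value


Scorer = Callable[[ScoredRecord], float]


def mock_scorer(stage: str, seed: int = 0) -> Scorer:
    """Deterministic pseudo-docking scorer: a stable hash of (stage, seed, id)
    mapped to a negative kcal/mol-like range.  Injective in practice (128-bit
    hash), reproducible across runs and platforms."""

    def score(record: ScoredRecord) -> float:
        h = hashlib.md5(f"{stage}:{seed}:{record.id}".encode()).hexdigest()
        u = int(h, 16) / 16 ** 32  # uniform in [0, 1)
        return -14.0 + 8.0 * u

    return score


def column_scorer(stage: str) -> Scorer:
    """Scorer that reads the stage's score from the record itself (e.g. a
    CSV of exported docking results)."""

    def score(record: ScoredRecord) -> float:
        return record.score(stage)

    return score


@dataclass(frozen=True)
class FunnelStage:
    """A named stage: score all inputs, keep the top ``retention_fraction``."""

    name: str
    retention_fraction: float
    scorer: Scorer | None = None
    higher_is_better: bool = False

    def __post_init__(self):
        if not (0 < self.retention_fraction <= 1):
            raise FunnelError("retention_fraction must be in (0, 1]")


@dataclass
class StageLog:
    name: str
    n_in: int
    n_retained: int


@dataclass
class FunnelResult:
    """Per-stage attrition log and the final ranked survivors."""

    stages: list[StageLog]
    records: list[ScoredRecord]

    @property
    def counts(self) -> list[tuple[str, int, int]]:
        return [(s.name, s.n_in, s.n_retained) for s in self.stages]


def retained_count(n: int, fraction: float) -> int:
    """Ceiling retention rule: keep ⌈fraction·N⌉ of N."""
    return math.ceil(fraction * n)


def run_stage(records: Sequence[ScoredRecord], stage: FunnelStage) -> list[ScoredRecord]:
    """Score, sort (best first, ties by id) and keep the top ⌈fraction·N⌉.

    When the stage has a scorer, each record's ``scores[stage.name]`` is
    (re)computed with it; otherwise the score must already be present.
    """
    scored: list[ScoredRecord] = []
    for r in records:
        if stage.scorer is not None:
            value = stage.scorer(r)
            r = replace(r, scores={**r.scores, stage.name: value})
        else:
            r.score(stage.name)
        scored.append(r)
    sign = -1.0 if stage.higher_is_better else 1.0
    scored.sort(key=lambda r: (sign * r.score(stage.name), r.id))
    return scored[: retained_count(len(scored), stage.retention_fraction)]


def run_funnel(records: Sequence[ScoredRecord], stages: Sequence[FunnelStage]) -> FunnelResult:
    """Apply stages in order, logging attrition; an empty survivor set simply
    short-circuits with zero final records."""
    if not stages:
        raise FunnelError("need at least one stage")
    log: list[StageLog] = []
    current = list(records)
    for stage in stages:
        n_in = len(current)
        current = run_stage(current, stage) if current else []
        log.append(StageLog(stage.name, n_in, len(current)))
    return FunnelResult(log, current)


def apply_threshold(
    records: Iterable[ScoredRecord], field_name: str, cutoff: float
) -> list[ScoredRecord]:
    """Keep records whose ``field_name`` (an attribute like 'affinity' or a
    stage score) is ≤ cutoff."""
    out = []
    for r in records:
        if field_name in r.scores:
            value = r.scores[field_name]
        else:
            value = getattr(r, field_name, None)
        if value is None:
            raise FunnelError(f"record {r.id!r} is missing field {field_name!r}")
        if value <= cutoff:
            out.append(r)
    return out


def rank_table(
    records: Sequence[ScoredRecord],
    primary: str,
    columns: Sequence[str] = (),
) -> pd.DataFrame:
    """Ranking report sorted ascending by the primary score column.

    ``primary`` and ``columns`` name stage scores or record attributes
    ('mw', 'affinity').  Ties break by id, so the table is stable under
    shuffling of the input.
    """

    def value(r: ScoredRecord, name: str):
        if name in r.scores:
            return r.scores[name]
        return getattr(r, name, None)

    rows = []
    for r in records:
        row = {"id": r.id}
        if r.smiles is not None:
            row["smiles"] = r.smiles
        for c in (primary, *columns):
            row[c] = value(r, c)
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values([primary, "id"], kind="mergesort").reset_index(drop=True)


# ------------------------------------------------------------------ CSV I/O

def records_from_csv(path) -> list[ScoredRecord]:
    """Read candidates from CSV: columns ``id`` (required), ``smiles``,
    ``mw``, ``mmgbsa`` (becomes affinity), and any ``score_*`` columns as
    stage scores keyed by the suffix."""
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        scores = {
            c[len("score_"):]: float(row[c])
            for c in df.columns
            if c.startswith("score_") and pd.notna(row[c])
        }
        records.append(
            ScoredRecord(
                id=str(row["id"]),
                smiles=row.get("smiles") if isinstance(row.get("smiles"), str) else None,
                scores=scores,
                affinity=float(row["mmgbsa"]) if "mmgbsa" in df.columns and pd.notna(row["mmgbsa"]) else None,
                mw=float(row["mw"]) if "mw" in df.columns and pd.notna(row["mw"]) else None,
            )
        )
    return records


def records_to_csv(records: Sequence[ScoredRecord], path) -> None:
    rows = []
    for r in records:
        row = {"id": r.id, "smiles": r.smiles, "mw": r.mw, "mmgbsa": r.affinity}
        for stage, value in r.scores.items():
            row[f"score_{stage}"] = value
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
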