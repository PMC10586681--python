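"""Token normalization, merging and the frequency/participation filters.

The preprocessing chain runs in a fixed order:

    normalize -> merge -> drop "other" category -> drop rare tokens
    -> drop participants left with no tokens -> select common emotion labels

Each step is idempotent, and the rare-token filter is driven by
participant counts (a participant mentioning a token twice counts once),
because the participant is the sampling unit of the co-occurrence model.
"""

from __future__ import annotations

import unicodedata

import pandas as pd

from .datatypes import (
    OTHER_CATEGORY,
    Corpus,
    MergeMap,
    PipelineConfig,
    ResponseRecord,
    ValidationError,
)

__all__ = [
    "InvalidTokenError",
    "normalize_token",
    "normalize_corpus",
    "apply_merge_map",
    "drop_other_category",
    "filter_rare_tokens",
    "drop_unclassifiable_participants",
    "filter_emotion_labels",
    "frequency_rank_report",
    "preprocess_corpus",
]


class InvalidTokenError(ValidationError):
    """A token normalizes to the empty string."""


def normalize_token(raw: str) -> str:
    """Lower-case, strip accents and trim a raw association token.

    Internal runs of whitespace collapse to single spaces so that
    multi-word expressions normalize stably.  An all-whitespace input has
    no canonical form and raises :class:`InvalidTokenError`.
    """
    decomposed = unicodedata.normalize("NFKD", raw)
    stripped = "".join(ch for ch in decomposed if not unicodedata.combining(ch))
    token = " ".join(stripped.lower().split())
    if not token:
        raise InvalidTokenError(f"token {raw!r} normalizes to empty string")
    return token


def _replace_tokens(corpus: Corpus, fn, step: str) -> Corpus:
    records = [
        ResponseRecord(
            participant_id=rec.participant_id,
            associations=tuple(fn(tok) for tok in rec.associations),
            emotion_labels=rec.emotion_labels,
            category=rec.category,
            intensity_raw=rec.intensity_raw,
        )
        for rec in corpus.records
    ]
    return corpus.with_records(records, step)


def normalize_corpus(corpus: Corpus) -> Corpus:
    return _replace_tokens(corpus, normalize_token, "normalize")


def apply_merge_map(corpus: Corpus, merge_map: MergeMap) -> Corpus:
    """Replace every token by its canonical form; the lexicon never grows."""
    return _replace_tokens(corpus, merge_map, "merge")


def drop_other_category(corpus: Corpus) -> tuple[Corpus, int]:
    """Remove participants whose category is "other".

    Whether their associations concern a substance or a behavior is
    unknowable, so they cannot enter the category-level inference.
    Returns the filtered corpus and the number of removed participants.
    """
    kept = [r for r in corpus.records if r.category != OTHER_CATEGORY]
    return corpus.with_records(kept, "drop_other"), len(corpus.records) - len(kept)


def filter_rare_tokens(corpus: Corpus, min_count: int) -> tuple[Corpus, float]:
    """Drop tokens mentioned by fewer than ``min_count`` participants.

    Rare tokens are treated as idiosyncratic and removed from every
    record (arity may fall below five; emotion-label pairs stay aligned
    with the surviving associations).  Returns the filtered corpus and
    the coverage fraction: retained association mentions over total
    mentions before filtering.
    """
    if min_count < 1:
        raise ValidationError("min_count must be >= 1")
    keep = {tok for tok, cnt in corpus.lexicon.items() if cnt >= min_count}
    total = corpus.total_mentions()
    records = []
    retained_mentions = 0
    for rec in corpus.records:
        idx = [k for k, tok in enumerate(rec.associations) if tok in keep]
        retained_mentions += len(idx)
        records.append(
            ResponseRecord(
                participant_id=rec.participant_id,
                associations=tuple(rec.associations[k] for k in idx),
                emotion_labels=tuple(rec.emotion_labels[k] for k in idx),
                category=rec.category,
                intensity_raw=rec.intensity_raw,
            )
        )
    coverage = retained_mentions / total if total else 0.0
    return corpus.with_records(records, "filter_rare"), coverage


def drop_unclassifiable_participants(corpus: Corpus) -> tuple[Corpus, int]:
    """Remove participants who retain no tokens after the rare filter."""
    kept = [r for r in corpus.records if r.associations]
    return corpus.with_records(kept, "drop_unclassifiable"), len(corpus.records) - len(kept)


def filter_emotion_labels(
    corpus: Corpus, threshold: float
) -> tuple[list[str], list[str]]:
    """Select labels provided by at least ``threshold`` of participants.

    A participant "provides" a label if it appears anywhere among the
    (up to ten) selections attached to their retained associations; the
    comparison is inclusive, so a label at exactly the threshold is kept.
    Returns (retained, excluded) label lists in schedule order.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError("threshold must lie in [0, 1]")
    n = corpus.n_participants
    providers: dict[str, int] = {lab: 0 for lab in corpus.label_list}
    for rec in corpus.records:
        seen = {lab for pair in rec.emotion_labels for lab in pair}
        for lab in seen:
            providers[lab] += 1
    retained = [lab for lab in corpus.label_list if n and providers[lab] / n >= threshold]
    excluded = [lab for lab in corpus.label_list if lab not in retained]
    return retained, excluded


def frequency_rank_report(corpus: Corpus) -> pd.DataFrame:
    """Rank tokens by participant frequency (threshold diagnostic).

    Plotting count against rank shows whether a breakpoint separates
    shared vocabulary from idiosyncratic tail — the usual way to justify
    a minimum-count cutoff.
    """
    items = sorted(corpus.lexicon.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        {
            "rank": range(1, len(items) + 1),
            "token": [t for t, _ in items],
            "participant_count": [c for _, c in items],
        }
    )


def preprocess_corpus(
    corpus: Corpus,
    config: PipelineConfig,
    merge_map: MergeMap | None = None,
) -> tuple[Corpus, list[str], dict]:
    """Run the full preprocessing chain.

    Returns the filtered corpus, the retained emotion labels, and a
    report dict with removal counts and the coverage fraction.
    """
    report: dict = {"n_input": corpus.n_participants}
    corpus = normalize_corpus(corpus)
    if merge_map is not None:
        corpus = apply_merge_map(corpus, merge_map)
    report["n_unique_tokens_merged"] = corpus.n_tokens
    corpus, n_other = drop_other_category(corpus)
    report["n_other_removed"] = n_other
    corpus, coverage = filter_rare_tokens(corpus, config.min_token_count)
    report["coverage"] = coverage
    report["n_tokens_retained"] = corpus.n_tokens
    corpus, n_unclass = drop_unclassifiable_participants(corpus)
    report["n_unclassifiable_removed"] = n_unclass
    report["n_participants_retained"] = corpus.n_participants
    retained, excluded = filter_emotion_labels(corpus, config.emotion_label_threshold)
    report["labels_retained"] = retained
    report["labels_excluded"] = excluded
    corpus.check_invariants(min_count=config.min_token_count)
    return corpus, retained, report
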