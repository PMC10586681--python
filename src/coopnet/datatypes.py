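"""Core record types for the free-word-association pipeline.

A participant contributes exactly five free associations to a cue about
their most disturbing excessive activity, tags each association with two
emotion labels from a fixed 20-label affect schedule, names the substance
or behavior they had in mind (4 substances, 10 behaviors, or "other"),
and rates problem intensity on a 4-point Likert item.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import yaml

__all__ = [
    "EMOTION_LABELS",
    "POSITIVE_LABELS",
    "NEGATIVE_LABELS",
    "SUBSTANCE_CATEGORIES",
    "BEHAVIOR_CATEGORIES",
    "OTHER_CATEGORY",
    "ALL_CATEGORIES",
    "N_ASSOCIATIONS",
    "N_LABELS_PER_ASSOCIATION",
    "ValidationError",
    "FormatError",
    "ResponseRecord",
    "MergeMap",
    "Corpus",
    "PipelineConfig",
]

#: Number of free associations elicited per participant.
N_ASSOCIATIONS = 5
#: Number of emotion labels attached to each association.
N_LABELS_PER_ASSOCIATION = 2

#: Default 20-item emotion-label schedule (10 positive, 10 negative affects).
POSITIVE_LABELS = (
    "joy",
    "calmness",
    "interest",
    "excitement",
    "enthusiasm",
    "pride",
    "inspiration",
    "determination",
    "attentiveness",
    "activity",
)
NEGATIVE_LABELS = (
    "worries",
    "shame",
    "anxiety",
    "contempt",
    "guilt",
    "fear",
    "hostility",
    "irritability",
    "nervousness",
    "distress",
)
EMOTION_LABELS = POSITIVE_LABELS + NEGATIVE_LABELS

SUBSTANCE_CATEGORIES = (
    "alcohol",
    "tobacco",
    "cannabis",
    "other substance",
)
BEHAVIOR_CATEGORIES = (
    "social media",
    "internet",
    "tv series",
    "eating",
    "work",
    "pornography",
    "shopping",
    "gaming",
    "sex",
    "gambling",
)
OTHER_CATEGORY = "other"
ALL_CATEGORIES = SUBSTANCE_CATEGORIES + BEHAVIOR_CATEGORIES + (OTHER_CATEGORY,)

#: Ordinal intensity codes of the single problem-severity item.
INTENSITY_LEVELS = {
    1: "Totally disagree",
    2: "Partly disagree",
    3: "Partly agree",
    4: "Totally agree",
}


class ValidationError(ValueError):
    """A record or corpus violates a structural invariant."""


class FormatError(ValueError):
    """An input file does not have the expected layout."""


@dataclass(frozen=True)
class ResponseRecord:
    """One participant's survey response.

    ``associations`` holds canonical (or raw) tokens in elicitation order;
    ``emotion_labels[k]`` is the pair of labels attached to
    ``associations[k]``.  After rare-token filtering a record may retain
    fewer than five associations; label pairs stay aligned.
    """

    participant_id: str
    associations: tuple[str, ...]
    emotion_labels: tuple[tuple[str, str], ...]
    category: str
    intensity_raw: int

    def token_set(self) -> frozenset[str]:
        """Distinct tokens of this participant (duplicates collapsed).

        The participant is the co-occurrence unit: a token repeated within
        one response still counts once toward frequencies and pair tables.
        """
        return frozenset(self.associations)

    def validate(
        self,
        label_list: tuple[str, ...] = EMOTION_LABELS,
        categories: tuple[str, ...] = ALL_CATEGORIES,
        require_full_arity: bool = True,
    ) -> None:
        pid = self.participant_id
        if not pid:
            raise ValidationError("participant_id must be non-empty")
        if require_full_arity and len(self.associations) != N_ASSOCIATIONS:
            raise ValidationError(
                f"participant {pid!r}: expected {N_ASSOCIATIONS} associations, "
                f"got {len(self.associations)}"
            )
        if len(self.emotion_labels) != len(self.associations):
            raise ValidationError(
                f"participant {pid!r}: {len(self.emotion_labels)} label pairs "
                f"for {len(self.associations)} associations"
            )
        for tok in self.associations:
            if not tok or not tok.strip():
                raise ValidationError(f"participant {pid!r}: empty association token")
        label_set = set(label_list)
        for k, pair in enumerate(self.emotion_labels):
            if len(pair) != N_LABELS_PER_ASSOCIATION or len(set(pair)) != N_LABELS_PER_ASSOCIATION:
                raise ValidationError(
                    f"participant {pid!r}: association {k + 1} needs "
                    f"{N_LABELS_PER_ASSOCIATION} distinct emotion labels"
                )
            for lab in pair:
                if lab not in label_set:
                    raise ValidationError(
                        f"participant {pid!r}: unknown emotion label {lab!r}"
                    )
        if self.category not in categories:
            raise ValidationError(f"participant {pid!r}: unknown category {self.category!r}")
        if self.intensity_raw not in INTENSITY_LEVELS:
            raise ValidationError(
                f"participant {pid!r}: intensity must be in 1..4, got {self.intensity_raw}"
            )


class MergeMap:
    """Many-to-one map from raw token to canonical token.

    Idempotent by construction: every canonical target maps to itself, so
    applying the map twice equals applying it once.  Tokens absent from the
    map pass through unchanged.
    """

    def __init__(self, mapping: dict[str, str] | None = None):
        self._map: dict[str, str] = {}
        for raw, canon in (mapping or {}).items():
            if not canon or not canon.strip():
                raise ValidationError(f"merge target for {raw!r} is empty")
            self._map[raw] = canon
        # close under idempotence
        for canon in list(self._map.values()):
            existing = self._map.get(canon)
            if existing is not None and existing != canon:
                raise ValidationError(
                    f"merge map not idempotent: {canon!r} -> {existing!r}"
                )
            self._map[canon] = canon

    def __call__(self, token: str) -> str:
        return self._map.get(token, token)

    def __len__(self) -> int:
        return len(self._map)

    def __eq__(self, other) -> bool:
        return isinstance(other, MergeMap) and self._map == other._map

    def as_dict(self) -> dict[str, str]:
        return dict(self._map)


@dataclass
class Corpus:
    """A validated collection of responses plus the canonical lexicon.

    ``lexicon`` maps canonical token -> number of participants mentioning
    it at least once.  ``applied_filters`` records which preprocessing
    steps have run, in order.
    """

    records: list[ResponseRecord]
    label_list: tuple[str, ...] = EMOTION_LABELS
    applied_filters: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.lexicon: dict[str, int] = self._count_lexicon()

    def _count_lexicon(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.records:
            for tok in rec.token_set():
                counts[tok] = counts.get(tok, 0) + 1
        return dict(sorted(counts.items()))

    def refresh_lexicon(self) -> None:
        self.lexicon = self._count_lexicon()

    @property
    def n_participants(self) -> int:
        return len(self.records)

    @property
    def n_tokens(self) -> int:
        return len(self.lexicon)

    def total_mentions(self) -> int:
        """Total association slots (duplicates within a participant count)."""
        return sum(len(r.associations) for r in self.records)

    def check_invariants(self, min_count: int | None = None) -> None:
        if self.lexicon != self._count_lexicon():
            raise ValidationError("lexicon counts out of sync with records")
        if min_count is not None:
            bad = {t: c for t, c in self.lexicon.items() if c < min_count}
            if bad:
                raise ValidationError(f"lexicon counts below {min_count}: {bad}")

    def with_records(self, records: list[ResponseRecord], step: str | None = None) -> "Corpus":
        filters = self.applied_filters + ([step] if step else [])
        return Corpus(records=records, label_list=self.label_list, applied_filters=filters)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Corpus)
            and self.records == other.records
            and self.label_list == other.label_list
        )


def _default_category_kinds() -> dict[str, str]:
    kinds = {c: "substance" for c in SUBSTANCE_CATEGORIES}
    kinds.update({c: "behavior" for c in BEHAVIOR_CATEGORIES})
    kinds[OTHER_CATEGORY] = "other"
    return kinds


def _default_valence() -> dict[str, str]:
    val = {lab: "positive" for lab in POSITIVE_LABELS}
    val.update({lab: "negative" for lab in NEGATIVE_LABELS})
    return val


@dataclass
class PipelineConfig:
    """Tunable parameters of the whole pipeline.

    min_token_count
        A token is retained only if at least this many participants
        mention it (default 10, the idiosyncrasy cutoff).
    emotion_label_threshold
        A label is analyzed only if at least this fraction of retained
        participants provide it anywhere among their ten selections
        (default 0.50, inclusive).
    consensus_runs / consensus_threshold / consensus_max_iter
        Number of Louvain restarts, the co-classification fraction below
        which a consensus edge is dropped (default 0.40), and the cap on
        re-clustering iterations.
    dunn_adjust
        Multiplicity adjustment for Dunn pairwise p-values: "none" or "holm".
    """

    min_token_count: int = 10
    emotion_label_threshold: float = 0.50
    consensus_runs: int = 100
    consensus_threshold: float = 0.40
    consensus_max_iter: int = 20
    random_seed: int = 0
    dunn_adjust: str = "none"
    label_list: tuple[str, ...] = EMOTION_LABELS
    category_kinds: dict[str, str] = field(default_factory=_default_category_kinds)
    label_valence: dict[str, str] = field(default_factory=_default_valence)

    def validate(self) -> None:
        if self.min_token_count < 1:
            raise ValidationError("min_token_count must be >= 1")
        if not 0.0 <= self.emotion_label_threshold <= 1.0:
            raise ValidationError("emotion_label_threshold must lie in [0, 1]")
        if not 0.0 < self.consensus_threshold < 1.0:
            raise ValidationError("consensus_threshold must lie in (0, 1)")
        if self.consensus_runs < 2:
            raise ValidationError("consensus_runs must be >= 2")
        if self.consensus_max_iter < 1:
            raise ValidationError("consensus_max_iter must be >= 1")
        if self.dunn_adjust not in ("none", "holm"):
            raise ValidationError("dunn_adjust must be 'none' or 'holm'")
        missing = set(self.label_list) - set(self.label_valence)
        if missing:
            raise ValidationError(f"labels without valence mapping: {sorted(missing)}")

    def replace(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)

    def to_yaml(self) -> str:
        d = {
            "min_token_count": self.min_token_count,
            "emotion_label_threshold": self.emotion_label_threshold,
            "consensus_runs": self.consensus_runs,
            "consensus_threshold": self.consensus_threshold,
            "consensus_max_iter": self.consensus_max_iter,
            "random_seed": self.random_seed,
            "dunn_adjust": self.dunn_adjust,
            "label_list": list(self.label_list),
            "category_kinds": dict(self.category_kinds),
            "label_valence": dict(self.label_valence),
        }
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text) or {}
        if "label_list" in d:
            d["label_list"] = tuple(d["label_list"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        """Short digest logged with every run for reproducibility."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]
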