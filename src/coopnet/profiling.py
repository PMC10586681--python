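"""Link participants to modules and summarize module composition.

A participant belongs to the module from which the plurality of their
retained associations came.  Module profiles collect the member tokens,
the relative emotion-label distribution of the member-token mentions,
and the participant composition by category kind and problem intensity.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .community import Partition
from .datatypes import Corpus, PipelineConfig, ValidationError

__all__ = [
    "ModuleProfile",
    "assign_participants",
    "emotion_distribution",
    "module_summary",
]


def assign_participants(
    corpus: Corpus, partition: Partition
) -> dict[str, int | None]:
    """Map each participant to a module by plurality of retained tokens.

    Ties are broken toward the module whose member tokens have the
    larger total corpus frequency (a fixed module-level quantity), then
    toward the lower module id.  Participants retaining no tokens map to
    ``None``.
    """
    membership = partition.membership
    missing = {t for r in corpus.records for t in r.token_set()} - set(membership)
    if missing:
        raise ValidationError(
            f"partition does not cover retained tokens: {sorted(missing)[:5]}"
        )
    # total corpus frequency of each module's member tokens (tie-break key)
    module_weight: dict[int, int] = {}
    for tok, mod in membership.items():
        module_weight[mod] = module_weight.get(mod, 0) + corpus.lexicon.get(tok, 0)

    out: dict[str, int | None] = {}
    for rec in corpus.records:
        toks = rec.token_set()
        if not toks:
            out[rec.participant_id] = None
            continue
        votes = Counter(membership[t] for t in toks)
        top = max(votes.values())
        tied = [m for m, v in votes.items() if v == top]
        out[rec.participant_id] = min(
            tied, key=lambda m: (-module_weight.get(m, 0), m)
        )
    return out


def emotion_distribution(
    corpus: Corpus,
    partition: Partition,
    retained_labels: list[str],
) -> dict[int, dict[str, float]]:
    """Relative percentage distribution of emotion labels per module.

    The counting unit is the (participant, association occurrence,
    label) triple: every retained label attached to a mention of a
    member token adds one count to that token's module.  Percentages
    within a module sum to 100; a module whose mentions carry no
    retained label gets an empty distribution.
    """
    membership = partition.membership
    keep = set(retained_labels)
    counts: dict[int, Counter] = {m: Counter() for m in set(membership.values())}
    for rec in corpus.records:
        for tok, pair in zip(rec.associations, rec.emotion_labels):
            mod = membership.get(tok)
            if mod is None:
                continue
            for lab in pair:
                if lab in keep:
                    counts[mod][lab] += 1
    out: dict[int, dict[str, float]] = {}
    for mod, ctr in sorted(counts.items()):
        total = sum(ctr.values())
        if total == 0:
            out[mod] = {}
        else:
            out[mod] = {
                lab: 100.0 * ctr[lab] / total for lab in retained_labels if ctr[lab]
            }
    return out


@dataclass
class ModuleProfile:
    """Composition summary of one module (one column of a cohort table)."""

    module_id: int
    n_participants: int
    top_tokens: list[tuple[str, int]]
    emotion_pct: dict[str, float]
    category_counts: dict[str, int]
    substance_pct: float  #: share of all substance users assigned here
    behavior_pct: float  #: share of all behavior users assigned here
    high_intensity_pct: float  #: share of this module's members at high intensity
    positive_affect_pct: float
    negative_affect_pct: float

    def to_dict(self) -> dict:
        return {
            "module_id": self.module_id,
            "n_participants": self.n_participants,
            "top_tokens": [[t, c] for t, c in self.top_tokens],
            "emotion_pct": self.emotion_pct,
            "category_counts": self.category_counts,
            "substance_pct": self.substance_pct,
            "behavior_pct": self.behavior_pct,
            "high_intensity_pct": self.high_intensity_pct,
            "positive_affect_pct": self.positive_affect_pct,
            "negative_affect_pct": self.negative_affect_pct,
        }


def module_summary(
    corpus: Corpus,
    partition: Partition,
    assignments: dict[str, int | None],
    config: PipelineConfig,
    retained_labels: list[str] | None = None,
    top_n: int = 5,
) -> list[ModuleProfile]:
    """Assemble per-module cohort profiles.

    Substance and behavior percentages are normalized within substance
    users and within behavior users respectively, so each of those two
    rows sums to 100 across modules.  High-intensity percentage is
    within-module (intensity 4 on the severity item).  Token ranking
    ties break alphabetically for stable output.
    """
    retained_labels = (
        retained_labels if retained_labels is not None else list(corpus.label_list)
    )
    modules = sorted(set(partition.membership.values()))
    emo = emotion_distribution(corpus, partition, retained_labels)
    rec_by_id = {r.participant_id: r for r in corpus.records}

    kind = config.category_kinds
    n_substance_total = sum(
        1
        for pid, m in assignments.items()
        if m is not None and kind.get(rec_by_id[pid].category) == "substance"
    )
    n_behavior_total = sum(
        1
        for pid, m in assignments.items()
        if m is not None and kind.get(rec_by_id[pid].category) == "behavior"
    )

    profiles = []
    members = partition.module_members()
    for mod in modules:
        pids = [pid for pid, m in assignments.items() if m == mod]
        recs = [rec_by_id[p] for p in pids]
        toks = sorted(
            ((t, corpus.lexicon.get(t, 0)) for t in members.get(mod, [])),
            key=lambda tc: (-tc[1], tc[0]),
        )
        cats = Counter(r.category for r in recs)
        n_sub = sum(c for cat, c in cats.items() if kind.get(cat) == "substance")
        n_beh = sum(c for cat, c in cats.items() if kind.get(cat) == "behavior")
        n_high = sum(1 for r in recs if r.intensity_raw == 4)
        dist = emo.get(mod, {})
        pos = sum(
            p for lab, p in dist.items() if config.label_valence.get(lab) == "positive"
        )
        neg = sum(
            p for lab, p in dist.items() if config.label_valence.get(lab) == "negative"
        )
        profiles.append(
            ModuleProfile(
                module_id=mod,
                n_participants=len(pids),
                top_tokens=toks[:top_n],
                emotion_pct=dist,
                category_counts=dict(sorted(cats.items())),
                substance_pct=100.0 * n_sub / n_substance_total if n_substance_total else 0.0,
                behavior_pct=100.0 * n_beh / n_behavior_total if n_behavior_total else 0.0,
                high_intensity_pct=100.0 * n_high / len(recs) if recs else 0.0,
                positive_affect_pct=pos,
                negative_affect_pct=neg,
            )
        )
    return profiles
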