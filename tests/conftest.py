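import pytest

from coopnet.datatypes import Corpus, ResponseRecord


def make_record(pid, tokens, category="alcohol", intensity=4, labels=None):
    """Build a record with placeholder emotion labels unless given."""
    if labels is None:
        labels = tuple(("joy", "worries") for _ in tokens)
    return ResponseRecord(
        participant_id=pid,
        associations=tuple(tokens),
        emotion_labels=tuple(labels),
        category=category,
        intensity_raw=intensity,
    )


@pytest.fixture
def tiny_corpus():
    """Four participants over a small shared vocabulary."""
    records = [
        make_record("p1", ["guilt", "shame", "stress", "calm", "relief"]),
        make_record("p2", ["guilt", "shame", "stress", "boredom", "fatigue"],
                    category="gaming", intensity=3),
        make_record("p3", ["guilt", "calm", "relief", "joy", "rest"],
                    category="eating", intensity=2),
        make_record("p4", ["guilt", "shame", "boredom", "fatigue", "waste"],
                    category="other", intensity=1),
    ]
    return Corpus(records=records)
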