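import pytest

import symtalk as st


@pytest.fixture(scope="session")
def lex() -> st.KeywordLibrary:
    return st.seed_lexicon()


@pytest.fixture()
def tiny_lib() -> st.KeywordLibrary:
    """Three-entry library with one exclusion, used across matcher tests."""
    return st.KeywordLibrary(
        entries=[
            st.make_entry("nausea", ["GI"]),
            st.make_entry("ativan", ["mood/anxiety"], is_medication=True),
            st.make_entry("fuzzy brain", ["neurological"]),
        ],
        exclusions=[st.ExclusionPattern("deep breaths", "exam instruction")],
        version_label="tiny-v1",
    )


def make_turn(text: str, index: int = 0, role: str = "patient") -> st.Turn:
    return st.Turn(turn_index=index, speaker_role=role, text=text)


def make_conversation(texts, cid="c1", pid="p1", dataset="test", metadata=None):
    return st.Conversation(
        conversation_id=cid,
        patient_id=pid,
        dataset_label=dataset,
        metadata=metadata or {},
        turns=[make_turn(t, i) for i, t in enumerate(texts)],
    )


@pytest.fixture()
def make_conv():
    return make_conversation
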