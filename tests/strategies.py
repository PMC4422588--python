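"""Shared hypothesis strategies for frequency vectors."""

from hypothesis import strategies as st

from abosim import AlleleFreqs


@st.composite
def allele_triples(draw, min_component=0.0):
    """Valid allele-frequency triples, optionally bounded away from zero."""
    lo = max(min_component, 1e-6)
    raw = draw(
        st.tuples(
            st.floats(lo, 1.0),
            st.floats(lo, 1.0),
            st.floats(lo, 1.0),
        )
    )
    s = sum(raw)
    return AlleleFreqs(raw[0] / s, raw[1] / s, raw[2] / s)


@st.composite
def boundary_triples(draw):
    """Triples that may have one or two components exactly zero."""
    raw = draw(
        st.tuples(
            st.floats(0.0, 1.0),
            st.floats(0.0, 1.0),
            st.floats(0.0, 1.0),
        ).filter(lambda t: sum(t) > 1e-6)
    )
    s = sum(raw)
    return AlleleFreqs(raw[0] / s, raw[1] / s, raw[2] / s)


selection_strengths = st.floats(0.0, 1.0)
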