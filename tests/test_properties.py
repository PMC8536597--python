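"""Property-based invariants (hypothesis, derandomised)."""

import numpy as np
from hypothesis import given, settings, strategies as st

from thermomca.elasticity import thermokinetic_elasticity
from thermomca.model_core import decompose

finite_coeff = st.floats(min_value=-3, max_value=3, allow_nan=False)


class TestThermokineticInvariants:
    @settings(derandomize=True, max_examples=60)
    @given(
        n=st.floats(min_value=-3, max_value=3).filter(lambda x: abs(x) > 1e-3),
        drg=st.floats(min_value=-60, max_value=-0.5),
        k=st.floats(min_value=0.1, max_value=10),
    )
    def test_linear_in_stoichiometry_inverse_in_energy(self, n, drg, k):
        base = thermokinetic_elasticity(n, drg)
        assert np.isclose(thermokinetic_elasticity(k * n, drg), k * base)
        assert np.isclose(thermokinetic_elasticity(n, k * drg), base / k)

    @settings(derandomize=True, max_examples=60)
    @given(
        n=st.floats(min_value=0.1, max_value=3),
        drg=st.floats(min_value=-60, max_value=-0.5),
    )
    def test_signs_follow_roles(self, n, drg):
        # substrate (negative stoichiometry) of a downhill reaction: positive
        assert thermokinetic_elasticity(-n, drg) > 0
        assert thermokinetic_elasticity(+n, drg) < 0


class TestDecompositionInvariants:
    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.lists(st.integers(min_value=-2, max_value=2),
                     min_size=3, max_size=3),
            min_size=2, max_size=6,
        )
    )
    def test_dependent_rows_reconstructed(self, rows):
        N = np.array(rows, dtype=float)
        if not np.any(N):
            return
        dec = decompose(N)
        assert len(dec.independent_idx) == np.linalg.matrix_rank(N)
        if len(dec.dependent_idx):
            recon = dec.conservation_basis @ dec.NR
            assert np.abs(recon - N[dec.dependent_idx]).max() < 1e-9
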