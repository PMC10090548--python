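import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ccmen import (
    BindingScoreSet,
    build_cbe_tables,
    compute_cbe,
    load_cbe_matrix,
    load_cbe_tables,
    zero_channel,
)
from ccmen.affinity import PAIRING_MAX
from ccmen.errors import StructureError
from ccmen.expression import table_from_frame

nonneg = st.floats(min_value=0, max_value=1e6, allow_nan=False)


class TestComputeCbe:
    @pytest.mark.parametrize(
        "args, expected",
        [
            ((2.0, 3.0, 5.0, 2.0, 1.5), 9.0),  # 2 * min(3,5) * min(2,1.5)
            ((0.0, 3.0, 5.0, 2.0, 1.5), 0.0),
            ((1.0, 1.0, 1.0, 1.0, 1.0), 1.0),
        ],
    )
    def test_examples(self, args, expected):
        assert compute_cbe(*args) == pytest.approx(expected)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            compute_cbe(-1.0, 1.0, 1.0, 1.0, 1.0)

    @given(bs=nonneg, a=nonneg, b=nonneg, c=nonneg, d=nonneg)
    def test_min_symmetry(self, bs, a, b, c, d):
        assert compute_cbe(bs, a, b, c, d) == compute_cbe(bs, b, a, d, c)

    @given(bs=nonneg, a=nonneg, b=nonneg, c=nonneg, d=nonneg,
           bump=st.floats(min_value=0, max_value=10))
    def test_monotone_in_each_argument(self, bs, a, b, c, d, bump):
        base = compute_cbe(bs, a, b, c, d)
        assert compute_cbe(bs + bump, a, b, c, d) >= base
        assert compute_cbe(bs, a + bump, b, c, d) >= base
        assert compute_cbe(bs, a, b, c + bump, d) >= base

    @given(bs=nonneg, a=nonneg, b=nonneg)
    def test_equal_pairs_collapse_to_product(self, bs, a, b):
        assert compute_cbe(bs, a, a, b, b) == pytest.approx(bs * a * b)


@pytest.fixture
def toy_expression():
    df = pd.DataFrame(
        {
            "gene": ["R1", "R2", "F1", "F2"],
            "role": ["receptor", "receptor", "factor", "factor"],
            "nex": [2.0, 4.0, 1.0, 8.0],
            "fc": [3.0, 0.5, 2.0, 1.5],
        }
    )
    return table_from_frame(df)


class TestBuildCbeTables:
    def test_hand_derived_entries(self, toy_expression):
        bs = BindingScoreSet(
            cell={1: 2.0, 2: 1.0},
            factor={(1, 1): 1.0, (2, 2): 3.0},
        )
        cbe = build_cbe_tables(bs, toy_expression)
        # GCC channel is homotypic: bs * nex * fc (both sides identical)
        assert cbe.gcc[1] == pytest.approx(2.0 * 2.0 * 3.0)
        assert cbe.gcc[2] == pytest.approx(1.0 * 4.0 * 0.5)
        # NHC channel caps the fold change at the normal-side reference of 1
        assert cbe.nhc[1] == pytest.approx(2.0 * 2.0 * 1.0)
        assert cbe.nhc[2] == pytest.approx(1.0 * 4.0 * 0.5)  # min(0.5, 1) = 0.5
        # factor channel pairs receptor with its cognate factor
        assert cbe.f[1] == pytest.approx(1.0 * min(2.0, 1.0) * min(3.0, 2.0))
        assert cbe.f[2] == pytest.approx(3.0 * min(4.0, 8.0) * min(0.5, 1.5))

    def test_zero_factor_scores_zero_channel(self, toy_expression):
        bs = BindingScoreSet(
            cell={1: 1.0, 2: 1.0}, factor={(1, 1): 0.0, (2, 2): 0.0}
        )
        cbe = build_cbe_tables(bs, toy_expression)
        assert all(v == 0 for v in cbe.f.values())

    def test_max_over_factors_picks_dominant_cross_score(self, toy_expression):
        bs = BindingScoreSet(
            cell={1: 1.0, 2: 1.0},
            factor={(1, 1): 1.0, (1, 2): 50.0, (2, 2): 3.0},
        )
        cbe = build_cbe_tables(bs, toy_expression, pairing=PAIRING_MAX)
        # brute-force the factor axis for receptor 1
        candidates = [
            1.0 * min(2.0, 1.0) * min(3.0, 2.0),
            50.0 * min(2.0, 8.0) * min(3.0, 1.5),
        ]
        assert cbe.f[1] == pytest.approx(max(candidates))

    def test_missing_receptor_score_is_lookup_error(self, toy_expression):
        bs = BindingScoreSet(cell={1: 1.0}, factor={(1, 1): 1.0})
        with pytest.raises(KeyError):
            build_cbe_tables(bs, toy_expression)


class TestCbeFiles:
    def test_vector_round_trip(self, tmp_path, make_cbe):
        cbe = make_cbe(n=5, seed=3)
        paths = cbe.write(tmp_path)
        again = load_cbe_tables(
            paths["cmcc.csv"], paths["cmnc.csv"], paths["cmf.csv"]
        )
        assert again == cbe or all(
            again.channel(ch)[c] == pytest.approx(cbe.channel(ch)[c])
            for ch in ("GCC", "NHC", "F")
            for c in cbe.codes
        )

    def test_all_ones_file(self, tmp_path):
        path = tmp_path / "ones.csv"
        path.write_text("\n".join(["1"] * 11) + "\n")
        channel = load_cbe_matrix(path)
        assert channel == {c: 1.0 for c in range(1, 12)}

    def test_square_matrix_diagonal_and_max(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("1,9\n2,4\n")
        assert load_cbe_matrix(path) == {1: 1.0, 2: 4.0}
        assert load_cbe_matrix(path, reduce="max") == {1: 9.0, 2: 4.0}

    def test_ragged_matrix_is_structure_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("1,2,3\n4,5,6\n")
        with pytest.raises(StructureError):
            load_cbe_matrix(path)

    def test_channel_length_mismatch(self, tmp_path):
        a = tmp_path / "a.csv"
        b = tmp_path / "b.csv"
        a.write_text("1\n2\n")
        b.write_text("1\n2\n3\n")
        with pytest.raises(StructureError):
            load_cbe_tables(a, a, b)

    def test_negative_entry_rejected(self, tmp_path):
        path = tmp_path / "neg.csv"
        path.write_text("1\n-2\n")
        with pytest.raises(StructureError):
            load_cbe_matrix(path)


def test_zero_channel_replaces_only_requested(toy_cbe):
    zeroed = zero_channel(toy_cbe, "NHC")
    assert all(v == 0 for v in zeroed.nhc.values())
    assert zeroed.gcc == toy_cbe.gcc and zeroed.f == toy_cbe.f
    with pytest.raises(KeyError):
        zero_channel(toy_cbe, "XYZ")
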