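"""MaxLFQ protein quantification and SILAC ratio formation."""

import numpy as np
import pandas as pd
import pytest

from nspquant import io, quant
from nspquant.simulate import SimDesign, generate_ground_truth, simulate_precursor_report

from conftest import brute_force_maxlfq, make_precursor_frame, random_peptide_matrix


class TestBuildPeptideMatrix:
    def test_fully_observed_shape(self):
        rows = [
            {"modified_sequence": seq, "channel": ch, "run": run, "ms2_quantity": 100.0}
            for seq in ("AAK", "CCK")
            for ch in ("L", "M", "H")
            for run in ("r1", "r2")
        ]
        frame = make_precursor_frame(rows)
        mat, precursors, cols = quant.build_peptide_matrix(frame, "P1")
        assert mat.shape == (2, 6)
        assert len(cols) == 6

    def test_duplicates_aggregate_by_max(self):
        frame = make_precursor_frame([{"ms2_quantity": 10.0}, {"ms2_quantity": 20.0}])
        mat, _, _ = quant.build_peptide_matrix(frame, "P1")
        assert mat.item() == 20.0

    def test_unknown_protein_raises(self):
        frame = make_precursor_frame([{}])
        with pytest.raises(LookupError, match="P999"):
            quant.build_peptide_matrix(frame, "P999")


class TestMaxLFQ:
    def test_single_precursor_two_columns_anchored(self):
        out = quant.maxlfq(np.array([[100.0, 200.0]]))
        np.testing.assert_allclose(out, [100.0, 200.0], rtol=1e-12)
        np.testing.assert_allclose(out.sum(), 300.0, rtol=1e-12)

    def test_consistent_twofold_ratios_recovered_exactly(self):
        # two precursors, three columns, perfectly consistent 1:2:4
        mat = np.array([[100.0, 200.0, 400.0], [50.0, 100.0, 200.0]])
        out = quant.maxlfq(mat)
        x = np.log2(out)
        np.testing.assert_allclose(x - x[0], [0.0, 1.0, 2.0], atol=1e-12)
        np.testing.assert_allclose(out, brute_force_maxlfq(mat), rtol=1e-9)

    def test_disconnected_columns_fall_back_to_summed_intensity(self):
        mat = np.array([[100.0, np.nan], [np.nan, 300.0], [np.nan, 50.0]])
        out = quant.maxlfq(mat)
        np.testing.assert_allclose(out, [100.0, 350.0])

    def test_matches_brute_force_oracle_on_random_matrices(self):
        rng = np.random.default_rng(42)
        n_checked = 0
        for _ in range(200):
            mat = random_peptide_matrix(rng)
            ours = quant.maxlfq(mat)
            oracle = brute_force_maxlfq(mat)
            np.testing.assert_allclose(ours, oracle, rtol=1e-9, equal_nan=True)
            n_checked += 1
        assert n_checked == 200

    def test_scale_equivariance_on_complete_consistent_matrix(self):
        # complete rank-1 intensities: the intensity anchor makes
        # column scaling exactly equivariant
        rng = np.random.default_rng(3)
        f = 2.0 ** rng.normal(10, 1, 5)[:, None]
        a = np.array([1.0, 2.0, 4.0, 8.0])[None, :]
        mat = f * a
        base = quant.maxlfq(mat)
        scaled = mat.copy()
        scaled[:, 2] *= 7.0
        out = quant.maxlfq(scaled)
        np.testing.assert_allclose(out[2] / base[2], 7.0, rtol=1e-9)
        np.testing.assert_allclose(out[[0, 1, 3]], base[[0, 1, 3]], rtol=1e-9)

    def test_column_scaling_shifts_log_ratios_with_missing_entries(self):
        # with missingness the anchor redistributes slightly, but the
        # fitted log abundance differences still shift by exactly log2(c)
        rng = np.random.default_rng(4)
        mat = 2.0 ** rng.normal(14, 2, size=(6, 4))
        mat[0, 1] = np.nan
        mat[3, 2] = np.nan
        base = np.log2(quant.maxlfq(mat))
        scaled = mat.copy()
        scaled[:, 2] *= 7.0
        out = np.log2(quant.maxlfq(scaled))
        np.testing.assert_allclose(
            (out[2] - out[0]) - (base[2] - base[0]), np.log2(7.0), rtol=1e-9
        )
        np.testing.assert_allclose(out[1] - out[0], base[1] - base[0], rtol=1e-9)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            quant.maxlfq(np.empty((0, 0)))
        with pytest.raises(ValueError):
            quant.maxlfq(np.array([[np.nan, np.nan]]))

    def test_min_shared_peptides_disconnects_weak_pairs(self):
        # one shared precursor between the two columns; min_shared=2 must
        # fall back to per-column sums
        mat = np.array([[100.0, 300.0], [50.0, np.nan]])
        connected = quant.maxlfq(mat, min_shared_peptides=1)
        assert np.isclose(connected.sum(), 450.0)
        split = quant.maxlfq(mat, min_shared_peptides=2)
        np.testing.assert_allclose(split, [150.0, 300.0])


class TestQuantifyAll:
    def test_noiseless_mix1_complete_quantification(self, noiseless_mix1_design):
        truth = generate_ground_truth(noiseless_mix1_design)
        table = _as_canonical(simulate_precursor_report(truth, noiseless_mix1_design))
        quants = quant.quantify_all(table)
        per_protein = quants.groupby("protein_group").size()
        n_cols = 3 * noiseless_mix1_design.n_replicates
        assert (per_protein == n_cols).all()

    def test_noiseless_ratios_equal_design_proportions_exactly(self, noiseless_mix1_design):
        truth = generate_ground_truth(noiseless_mix1_design)
        table = _as_canonical(simulate_precursor_report(truth, noiseless_mix1_design))
        for mode in ("joint", "per_channel"):
            quants = quant.quantify_all(table, mode=mode)
            ratios = quant.compute_ratios(quants, pair=("H", "L"))
            np.testing.assert_allclose(
                ratios.to_numpy(), np.log2(15 / 70), atol=1e-9
            )

    def test_protein_observed_in_single_channel_emits_only_that_channel(self):
        frame = make_precursor_frame(
            [{"channel": "H", "run": r, "modified_sequence": s}
             for r in ("r1", "r2") for s in ("AAK", "CCK")]
        )
        quants = quant.quantify_all(frame)
        assert set(quants["channel"]) == {"H"}

    def test_quant_source_selects_the_quantity_column(self):
        rows = [
            {"modified_sequence": s, "channel": ch, "run": "r1",
             "ms1_quantity": v, "ms2_quantity": v * 3}
            for s, v in (("AAK", 100.0), ("CCK", 200.0))
            for ch in ("H", "M")
        ]
        frame = make_precursor_frame(rows)
        q1 = quant.quantify_all(frame, quant_source="MS1")
        q2 = quant.quantify_all(frame, quant_source="MS2")
        np.testing.assert_allclose(
            q2["lfq_intensity"].to_numpy(), 3 * q1["lfq_intensity"].to_numpy(), rtol=1e-12
        )

    def test_precursor_count_ignores_channels_and_runs(self, small_filtered_table):
        quants = quant.quantify_all(small_filtered_table)
        expected = (
            small_filtered_table.assign(
                key=lambda d: d["modified_sequence"] + "/" + d["charge"].astype(str)
            )
            .groupby("protein_group")["key"]
            .nunique()
        )
        got = quants.drop_duplicates("protein_group").set_index("protein_group")["n_precursors"]
        pd.testing.assert_series_equal(got.sort_index(), expected.sort_index(), check_names=False)

    def test_empty_table_gives_empty_output(self):
        frame = make_precursor_frame([]).reindex(columns=io.COLUMNS)
        out = quant.quantify_all(frame)
        assert out.empty


class TestRatios:
    def test_simple_log2_ratio(self):
        quants = pd.DataFrame(
            {
                "protein_group": ["P1", "P1"],
                "sample": ["r1", "r1"],
                "channel": ["H", "M"],
                "lfq_intensity": [2000.0, 1000.0],
            }
        )
        ratios = quant.compute_ratios(quants, pair=("H", "M"))
        assert ratios.loc["P1", "r1"] == pytest.approx(1.0)

    def test_missing_denominator_gives_absent_ratio(self):
        quants = pd.DataFrame(
            {
                "protein_group": ["P1", "P2", "P2"],
                "sample": ["r1", "r1", "r1"],
                "channel": ["H", "H", "M"],
                "lfq_intensity": [2000.0, 100.0, 100.0],
            }
        )
        ratios = quant.compute_ratios(quants, pair=("H", "M"))
        assert np.isnan(ratios.loc["P1", "r1"]) if "P1" in ratios.index else True
        assert ratios.loc["P2", "r1"] == pytest.approx(0.0)

    def test_identical_channels_rejected(self):
        with pytest.raises(ValueError, match="channel"):
            quant.compute_ratios(pd.DataFrame(), pair=("H", "H"))

    def test_ratios_invariant_to_global_rescaling(self, small_filtered_table):
        quants = quant.quantify_all(small_filtered_table)
        scaled = small_filtered_table.copy()
        scaled["ms2_quantity"] = scaled["ms2_quantity"] * 1e3
        scaled.attrs = dict(small_filtered_table.attrs)
        quants2 = quant.quantify_all(scaled)
        r1 = quant.compute_ratios(quants, pair=("H", "M"))
        r2 = quant.compute_ratios(quants2, pair=("H", "M"))
        pd.testing.assert_frame_equal(r1, r2, check_exact=False, rtol=1e-9)

    def test_equimolar_mix_median_ratio_near_zero(self, small_filtered_table):
        # mix2: H and M both 40% -> expected log2 H/M = 0
        quants = quant.quantify_all(small_filtered_table)
        ratios = quant.compute_ratios(quants, pair=("H", "M"))
        assert abs(np.nanmedian(ratios.to_numpy())) < 0.05

    def test_noise_shrinks_with_precursor_count(self):
        # per-protein ratio SD should trend down as peptide coverage grows
        d = SimDesign(
            n_proteins=300, seed=77, noise_sd_log2=0.4,
            channel_proportions={"L": 0.2, "M": 0.4, "H": 0.4},
            peptides_per_protein_mean=6.0, missing_rate=0.0, decoy_rate=0.0,
        )
        truth = generate_ground_truth(d)
        table = _as_canonical(simulate_precursor_report(truth, d))
        quants = quant.quantify_all(table)
        ratios = quant.compute_ratios(quants, pair=("H", "M"))
        counts = quants.drop_duplicates("protein_group").set_index("protein_group")["n_precursors"]
        sd = ratios.std(axis=1, ddof=1)
        few = sd[counts.reindex(sd.index) <= 3]
        many = sd[counts.reindex(sd.index) >= 8]
        assert many.mean() < few.mean()


class TestPrecursorLabelRatio:
    def test_equal_intensities_give_zero_median(self):
        rows = [
            {"modified_sequence": s, "channel": ch, "run": "r1", "ms2_quantity": 500.0}
            for s in ("AAK", "CCK") for ch in ("L", "H")
        ]
        out = quant.precursor_label_ratio(make_precursor_frame(rows))
        assert out["log2_ratio"].median() == pytest.approx(0.0)

    def test_noiseless_mix2_hl_ratio_is_one(self):
        d = SimDesign(
            n_proteins=30, channel_proportions={"L": 0.2, "M": 0.4, "H": 0.4},
            noise_sd_log2=0.0, missing_rate=0.0, decoy_rate=0.0, seed=21,
        )
        truth = generate_ground_truth(d)
        table = _as_canonical(simulate_precursor_report(truth, d))
        out = quant.precursor_label_ratio(table)
        np.testing.assert_allclose(out.loc[out["channel"] == "H", "log2_ratio"], 1.0, atol=1e-12)

    def test_no_light_channel_gives_empty_distribution(self):
        rows = [{"modified_sequence": "AAK", "channel": "H", "run": "r1"}]
        out = quant.precursor_label_ratio(make_precursor_frame(rows))
        assert out.empty


def _as_canonical(report: pd.DataFrame) -> pd.DataFrame:
    """Rename a simulated DIA-NN-dialect report to canonical columns
    without a filesystem round trip."""
    renamed = report.rename(
        columns={
            "Protein.Group": "protein_group",
            "Genes": "gene",
            "Stripped.Sequence": "stripped_sequence",
            "Modified.Sequence": "modified_sequence",
            "Precursor.Charge": "charge",
            "Channel": "channel",
            "Run": "run",
            "Ms1.Translated": "ms1_quantity",
            "Precursor.Translated": "ms2_quantity",
            "Q.Value": "q_value",
            "Channel.Q.Value": "channel_q_value",
            "Translated.Q.Value": "translated_q_value",
        }
    )
    renamed.attrs["quant_source"] = "MS2"
    return renamed
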