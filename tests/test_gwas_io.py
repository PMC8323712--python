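"""Reader, harmonization, instrument selection and LD-pruning behaviour."""

import numpy as np
import pandas as pd
import pytest

from lipomr import gwas_io
from lipomr.containers import ConfigurationError, DataError, LDMatrix

from conftest import make_panel, make_stats


def _write(tmp_path, rows, name="stats.tsv", columns=None):
    cols = columns or ["variant_id", "effect_allele", "other_allele", "beta", "se",
                       "chrom", "pos", "eaf", "pvalue", "n"]
    df = pd.DataFrame(rows, columns=cols[: len(rows[0])])
    path = tmp_path / name
    df.to_csv(path, sep="\t", index=False)
    return path


WELL_FORMED = [
    ["rs1", "A", "G", 0.10, 0.01, "1", 100, 0.3, 1e-9, 1000],
    ["rs2", "C", "T", -0.05, 0.02, "1", 200, 0.4, 1e-3, 1000],
    ["rs3", "G", "A", 0.02, 0.01, "2", 300, 0.2, 0.5, 1000],
]


class TestReader:
    def test_well_formed_table_parses_identically(self, tmp_path):
        path = _write(tmp_path, WELL_FORMED)
        stats, report = gwas_io.read_summary_stats(path, "LDL-C")
        assert len(stats) == 3 and report.n_dropped == 0
        rec = stats.by_id()["rs1"]
        assert (rec.beta, rec.se, rec.effect_allele) == (0.10, 0.01, "A")
        assert rec.pos == 100 and rec.eaf == 0.3

    @pytest.mark.parametrize(
        "bad_row, reason",
        [
            (["rs9", "A", "G", 0.1, 0.0, "1", 1, 0.2, 0.1, 10], "nonpositive_se"),
            (["rs9", "AT", "G", 0.1, 0.01, "1", 1, 0.2, 0.1, 10], "invalid_alleles"),
            (["rs9", "A", "A", 0.1, 0.01, "1", 1, 0.2, 0.1, 10], "invalid_alleles"),
        ],
    )
    def test_bad_rows_dropped_and_counted(self, tmp_path, bad_row, reason):
        path = _write(tmp_path, WELL_FORMED + [bad_row])
        stats, report = gwas_io.read_summary_stats(path, "t")
        assert len(stats) == 3
        assert report.dropped == {reason: 1}

    def test_duplicate_variant_id_is_error_naming_id(self, tmp_path):
        path = _write(tmp_path, WELL_FORMED + [WELL_FORMED[0]])
        with pytest.raises(DataError, match="rs1"):
            gwas_io.read_summary_stats(path, "t")

    def test_missing_required_column_is_configuration_error(self, tmp_path):
        path = _write(tmp_path, [["rs1", "A", "G", 0.1]],
                      columns=["variant_id", "effect_allele", "other_allele", "beta"])
        with pytest.raises(ConfigurationError, match="se"):
            gwas_io.read_summary_stats(path, "t")

    def test_comma_delimiter_autodetected(self, tmp_path):
        path = tmp_path / "stats.csv"
        pd.DataFrame(WELL_FORMED, columns=["variant_id", "effect_allele", "other_allele",
                                           "beta", "se", "chrom", "pos", "eaf", "pvalue", "n"]
                     ).to_csv(path, index=False)
        stats, _ = gwas_io.read_summary_stats(path, "t")
        assert len(stats) == 3


def _rec(vid, ea, oa, beta, eaf=0.3, se=0.01, p=1e-9):
    return dict(variant_id=vid, effect_allele=ea, other_allele=oa, beta=beta,
                se=se, eaf=eaf, pvalue=p, chrom="1", pos=1)


class TestHarmonize:
    def test_allele_swap_flips_outcome_beta(self):
        exp = make_stats("X", [_rec("rs1", "A", "G", 0.2)])
        out = make_stats("Y", [_rec("rs1", "G", "A", 0.1)])
        panel = gwas_io.harmonize([exp], out)
        assert panel.bY[0] == pytest.approx(-0.1)
        assert panel.bX[0, 0] == pytest.approx(0.2)

    def test_palindromic_resolved_by_matching_eaf(self):
        # A/T variant, both eafs on the same side of 0.5 and beyond the
        # 0.08 threshold: retained and aligned without a flip
        exp = make_stats("X", [_rec("rs2", "A", "T", 0.2, eaf=0.10)])
        out = make_stats("Y", [_rec("rs2", "A", "T", 0.1, eaf=0.12)])
        panel = gwas_io.harmonize([exp], out, drop_palindromic=False, eaf_threshold=0.08)
        assert panel.variant_ids == ["rs2"]
        assert panel.bY[0] == pytest.approx(0.1)

    def test_palindromic_opposite_eaf_sides_flips_beta(self):
        exp = make_stats("X", [_rec("rs2", "A", "T", 0.2, eaf=0.10)])
        out = make_stats("Y", [_rec("rs2", "T", "A", 0.1, eaf=0.88)])
        panel = gwas_io.harmonize([exp], out, drop_palindromic=False)
        # outcome T-allele frequency 0.88 -> its A frequency 0.12 matches the
        # exposure's 0.10: a plain allele swap, so the beta flips sign
        assert panel.bY[0] == pytest.approx(-0.1)

    def test_palindromic_near_half_eaf_dropped(self):
        exp = make_stats("X", [_rec("rs2", "A", "T", 0.2, eaf=0.47),
                               _rec("rs3", "A", "G", 0.1)])
        out = make_stats("Y", [_rec("rs2", "A", "T", 0.1, eaf=0.46),
                               _rec("rs3", "A", "G", 0.2)])
        panel = gwas_io.harmonize([exp], out, drop_palindromic=False)
        assert panel.variant_ids == ["rs3"]

    def test_palindromic_dropped_by_default(self):
        exp = make_stats("X", [_rec("rs2", "A", "T", 0.2), _rec("rs3", "A", "G", 0.1)])
        out = make_stats("Y", [_rec("rs2", "A", "T", 0.1), _rec("rs3", "A", "G", 0.2)])
        panel = gwas_io.harmonize([exp], out)
        assert panel.variant_ids == ["rs3"]
        log = panel.alignment_log
        assert (log[log.variant_id == "rs2"].detail == "palindromic").all()

    def test_irreconcilable_alleles_dropped_with_log(self):
        exp = make_stats("X", [_rec("rs3", "A", "G", 0.1), _rec("rs4", "A", "G", 0.1)])
        out = make_stats("Y", [_rec("rs3", "A", "C", 0.1), _rec("rs4", "A", "G", 0.1)])
        panel = gwas_io.harmonize([exp], out)
        assert panel.variant_ids == ["rs4"]
        log = panel.alignment_log
        assert "allele mismatch" in set(log[log.variant_id == "rs3"].detail)

    def test_empty_intersection_is_data_error(self):
        exp = make_stats("X", [_rec("rs1", "A", "G", 0.1)])
        out = make_stats("Y", [_rec("rs2", "A", "G", 0.1)])
        with pytest.raises(DataError):
            gwas_io.harmonize([exp], out)

    def test_strand_flip_aligned_without_beta_flip(self):
        exp = make_stats("X", [_rec("rs5", "A", "G", 0.2)])
        out = make_stats("Y", [_rec("rs5", "T", "C", 0.1)])  # complement strand
        panel = gwas_io.harmonize([exp], out)
        assert panel.bY[0] == pytest.approx(0.1)

    def test_sign_consistency_under_global_allele_flip(self, rng):
        """Flipping both alleles and the beta sign of every outcome record
        leaves the harmonized panel numerically identical."""
        rows = [_rec(f"rs{i}", "A", "G", rng.normal()) for i in range(8)]
        exp = make_stats("X", rows)
        out_rows = [_rec(f"rs{i}", "A", "G", rng.normal()) for i in range(8)]
        out = make_stats("Y", out_rows)
        flipped = make_stats(
            "Y",
            [
                {**r, "effect_allele": "G", "other_allele": "A",
                 "beta": -r["beta"], "eaf": 1 - r["eaf"]}
                for r in out_rows
            ],
        )
        p1 = gwas_io.harmonize([exp], out)
        p2 = gwas_io.harmonize([exp], flipped)
        np.testing.assert_allclose(p1.bY, p2.bY)
        np.testing.assert_allclose(p1.bX, p2.bX)


class TestInstrumentSelection:
    def _panel(self, pvals):
        J = len(pvals)
        return make_panel(
            np.full(J, 0.1), 0.01, np.zeros(J), np.full(J, 0.05),
            pX=np.asarray(pvals, float).reshape(J, 1),
        )

    def test_threshold_is_strict(self):
        panel = self._panel([4e-9, 6e-8, 5e-8, 1e-10, 0.5])
        kept = gwas_io.select_instruments(panel, p_threshold=5e-8)
        assert kept.variant_ids == ["rs1", "rs4"]

    def test_p_equal_one_keeps_everything(self):
        panel = self._panel([0.1, 0.5, 0.99])
        kept = gwas_io.select_instruments(panel, p_threshold=1.0)
        assert kept.variant_ids == panel.variant_ids
        np.testing.assert_array_equal(kept.bX, panel.bX)

    def test_named_rule_with_absent_exposure_errors(self):
        panel = self._panel([1e-9])
        with pytest.raises(ConfigurationError):
            gwas_io.select_instruments(panel, rule="named_exposure", exposure="nope")


class TestLDPrune:
    def test_pairwise_exclusion_keeps_smaller_p(self):
        panel = make_panel([0.1, 0.1], 0.01, [0, 0], [0.05, 0.05],
                           pX=np.array([[1e-8], [1e-12]]))
        ld = LDMatrix(["rs1", "rs2"], np.array([[1, np.sqrt(0.5)], [np.sqrt(0.5), 1]]))
        kept = gwas_io.ld_prune(panel, ld, r2_threshold=0.1)
        assert kept.variant_ids == ["rs2"]

    def test_identity_ld_keeps_all(self):
        J = 6
        panel = make_panel(np.ones(J), 0.01, np.zeros(J), np.full(J, 0.05),
                           pX=np.linspace(1e-9, 1e-5, J).reshape(J, 1))
        kept = gwas_io.ld_prune(panel, LDMatrix.identity(panel.variant_ids), 0.01)
        assert kept.variant_ids == panel.variant_ids

    def test_greedy_trace_matches_hand_computation(self):
        # ranked order rs1 (best p) .. rs4; hand greedy trace at r2 < 0.1:
        # keep rs1; rs2 r2=0.3 with rs1 -> drop; rs3 r2=0.05,0.2 w/ rs1 kept
        # set {rs1} -> 0.05 < 0.1 keep; rs4 r2 vs rs1=0.08, vs rs3=0.25 -> drop
        r = np.sqrt(np.array([
            [1.00, 0.30, 0.05, 0.08],
            [0.30, 1.00, 0.20, 0.12],
            [0.05, 0.20, 1.00, 0.25],
            [0.08, 0.12, 0.25, 1.00],
        ]))
        np.fill_diagonal(r, 1.0)
        ld = LDMatrix([f"rs{i+1}" for i in range(4)], r)
        panel = make_panel([0.1] * 4, 0.01, [0] * 4, [0.05] * 4,
                           pX=np.array([[1e-12], [1e-10], [1e-8], [1e-6]]))
        kept = gwas_io.ld_prune(panel, ld, r2_threshold=0.1)
        assert kept.variant_ids == ["rs1", "rs3"]

    def test_survivors_are_mutually_independent(self, rng):
        J = 30
        A = rng.normal(size=(J, J))
        corr = np.corrcoef(A @ A.T)
        ld = LDMatrix([f"rs{i+1}" for i in range(J)], corr)
        panel = make_panel(np.ones(J), 0.01, np.zeros(J), np.full(J, 0.05),
                           pX=rng.uniform(size=(J, 1)))
        kept = gwas_io.ld_prune(panel, ld, r2_threshold=0.2)
        sub = ld.subset(kept.variant_ids).r
        off = sub[~np.eye(len(sub), dtype=bool)]
        assert (off**2 < 0.2).all()

    def test_variant_absent_from_ld_is_error(self):
        panel = make_panel([0.1], 0.01, [0.0], [0.05])
        with pytest.raises(DataError, match="rs1"):
            gwas_io.ld_prune(panel, LDMatrix(["other"], np.eye(1)), 0.1)


def test_harmonization_is_idempotent(rng):
    """Re-harmonizing the harmonized output changes nothing."""
    exp_rows = [_rec(f"rs{i}", "A", "G", rng.normal(), eaf=0.2) for i in range(6)]
    out_rows = [
        {**_rec(f"rs{i}", "G", "A", rng.normal(), eaf=0.8)} for i in range(6)
    ]
    exp, out = make_stats("X", exp_rows), make_stats("Y", out_rows)
    p1 = gwas_io.harmonize([exp], out)
    # rebuild stat sets from the harmonized panel (all on the exposure allele)
    exp2 = make_stats("X", [
        _rec(v, "A", "G", b) for v, b in zip(p1.variant_ids, p1.bX[:, 0])
    ])
    out2 = make_stats("Y", [
        _rec(v, "A", "G", b) for v, b in zip(p1.variant_ids, p1.bY)
    ])
    p2 = gwas_io.harmonize([exp2], out2)
    np.testing.assert_allclose(p1.bX, p2.bX)
    np.testing.assert_allclose(p1.bY, p2.bY)
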