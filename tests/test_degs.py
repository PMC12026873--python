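import math
import shutil
import subprocess
import textwrap

import numpy as np
import pytest
from scipy import stats

from netpharm.degs import (DEGRecord, ExpressionMatrix, ParseError,
                           build_disease_targets, collapse_probes,
                           differential_expression, filter_degs,
                           read_series_matrix, union_deg_sets,
                           write_series_matrix)


def matrix(values, n_case, n_control, probe_ids=None):
    values = np.asarray(values, dtype=float)
    samples = [f"S{i}" for i in range(n_case + n_control)]
    groups = {s: ("case" if i < n_case else "control")
              for i, s in enumerate(samples)}
    probes = probe_ids or [f"P{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(probe_ids=probes, sample_ids=samples,
                            values=values, groups=groups)


class TestSeriesMatrixIO:
    def test_round_trip(self, tmp_path, rng):
        m = matrix(rng.normal(8, 2, (30, 8)), 4, 4)
        write_series_matrix(m, tmp_path / "m.tsv",
                            groups_path=tmp_path / "g.tsv")
        back = read_series_matrix(tmp_path / "m.tsv",
                                  groups_path=tmp_path / "g.tsv")
        assert back.probe_ids == m.probe_ids
        assert back.sample_ids == m.sample_ids
        assert back.groups == m.groups
        np.testing.assert_allclose(back.values, m.values, rtol=1e-5)

    def test_groups_from_characteristics_lines(self, tmp_path, rng):
        m = matrix(rng.normal(8, 2, (5, 4)), 2, 2)
        write_series_matrix(m, tmp_path / "m.tsv")  # no sidecar
        back = read_series_matrix(tmp_path / "m.tsv")
        assert back.groups == m.groups

    def test_unlogged_values_transformed_with_warning(self, tmp_path):
        m = matrix(np.full((3, 4), 9.0), 2, 2)
        write_series_matrix(m, tmp_path / "m.tsv",
                            groups_path=tmp_path / "g.tsv")
        # rewrite the table with raw-scale values
        text = (tmp_path / "m.tsv").read_text().replace("\t9\t", "\t12000\t")
        (tmp_path / "m.tsv").write_text(text)
        with pytest.warns(UserWarning, match="log2"):
            back = read_series_matrix(tmp_path / "m.tsv",
                                      groups_path=tmp_path / "g.tsv")
        assert back.values.max() <= math.log2(12001)

    def test_sample_missing_from_sidecar(self, tmp_path, rng):
        m = matrix(rng.normal(8, 2, (3, 4)), 2, 2)
        write_series_matrix(m, tmp_path / "m.tsv",
                            groups_path=tmp_path / "g.tsv")
        (tmp_path / "g.tsv").write_text("sample_id\tgroup\nS0\tcase\n")
        with pytest.raises(ParseError, match="absent"):
            read_series_matrix(tmp_path / "m.tsv",
                               groups_path=tmp_path / "g.tsv")

    def test_missing_markers(self, tmp_path):
        (tmp_path / "m.tsv").write_text("ID_REF\tS0\nP1\t3.0\n")
        with pytest.raises(ParseError, match="marker"):
            read_series_matrix(tmp_path / "m.tsv")

    def test_ragged_row_reports_line_number(self, tmp_path, rng):
        m = matrix(rng.normal(8, 2, (3, 4)), 2, 2)
        write_series_matrix(m, tmp_path / "m.tsv",
                            groups_path=tmp_path / "g.tsv")
        lines = (tmp_path / "m.tsv").read_text().splitlines()
        bad = next(i for i, ln in enumerate(lines) if ln.startswith("P1"))
        lines[bad] = lines[bad] + "\textra"
        (tmp_path / "m.tsv").write_text("\n".join(lines) + "\n")
        with pytest.raises(ParseError, match=str(bad + 1)):
            read_series_matrix(tmp_path / "m.tsv",
                               groups_path=tmp_path / "g.tsv")


class TestDifferentialExpression:
    def test_identical_groups(self):
        row = [5.0, 6.0, 7.0, 5.0, 6.0, 7.0]
        rec = differential_expression(matrix([row], 3, 3), "welch")[0]
        assert rec.logfc == 0.0 and rec.p == pytest.approx(1.0)

    def test_welch_matches_hand_computation(self):
        """Fixed 3-vs-3 example against a hand-evaluated Welch t and
        Satterthwaite df."""
        case = np.array([10.0, 11.0, 12.5])
        ctrl = np.array([9.0, 9.5, 10.2])
        rec = differential_expression(matrix([list(case) + list(ctrl)], 3, 3),
                                      "welch")[0]
        v1, v2 = case.var(ddof=1), ctrl.var(ddof=1)
        se2 = v1 / 3 + v2 / 3
        t = (case.mean() - ctrl.mean()) / math.sqrt(se2)
        df = se2**2 / ((v1 / 3)**2 / 2 + (v2 / 3)**2 / 2)
        p = 2 * stats.t.sf(abs(t), df)
        assert rec.logfc == pytest.approx(case.mean() - ctrl.mean())
        assert rec.p == pytest.approx(p, rel=1e-10)

    def test_welch_zero_variance_degenerate_convention(self):
        rec = differential_expression(
            matrix([[5.0, 5.0, 7.0, 7.0]], 2, 2), "welch")[0]
        assert rec.degenerate and rec.p == 0.0
        rec = differential_expression(
            matrix([[5.0, 5.0, 5.0, 5.0]], 2, 2), "welch")[0]
        assert rec.degenerate and rec.p == 1.0

    def test_moderated_d0_zero_equals_pooled_t(self, rng):
        x = rng.normal(8, 1, (50, 12))
        m = matrix(x, 6, 6)
        recs = differential_expression(m, "moderated", d0_override=0.0)
        ref = stats.ttest_ind(x[:, :6], x[:, 6:], axis=1, equal_var=True)
        np.testing.assert_allclose([r.p for r in recs], ref.pvalue, atol=1e-6)

    def test_moderated_matches_limma(self, tmp_path, rng):
        """Independent cross-check against limma's eBayes moderated t."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        n, n1, n2 = 150, 6, 6
        sd = np.exp(rng.normal(-0.7, 0.4, (n, 1)))
        x = rng.normal(8, 2, (n, 1)) + rng.normal(0, 1, (n, n1 + n2)) * sd
        x[:15, :n1] += 1.5
        np.savetxt(tmp_path / "mat.tsv", x, delimiter="\t")
        recs = differential_expression(matrix(x, n1, n2), "moderated")
        script = textwrap.dedent("""
            suppressMessages(library(limma))
            x <- as.matrix(read.table('mat.tsv'))
            design <- cbind(Intercept=1, case=c(rep(1,6), rep(0,6)))
            fit <- eBayes(lmFit(x, design))
            write.table(fit$p.value[, 'case'], 'r_p.tsv',
                        row.names=FALSE, col.names=FALSE)
        """)
        (tmp_path / "run.R").write_text(script)
        subprocess.run(["Rscript", "run.R"], cwd=tmp_path, check=True,
                       capture_output=True)
        r_p = np.loadtxt(tmp_path / "r_p.tsv")
        np.testing.assert_allclose([r.p for r in recs], r_p, atol=1e-9)

    def test_planted_probes_rank_above_null(self, rng):
        x = rng.normal(8, 0.5, (200, 20))
        x[:20, :10] += 2.0
        m = matrix(x, 10, 10)
        for method in ("welch", "moderated"):
            recs = differential_expression(m, method)
            order = np.argsort([r.p for r in recs])
            assert set(order[:20]) == set(range(20))

    def test_direction_matches_logfc_sign(self, rng):
        recs = differential_expression(matrix(rng.normal(8, 1, (50, 8)), 4, 4))
        for r in recs:
            assert r.direction == ("up" if r.logfc >= 0 else "down")

    def test_small_groups_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            differential_expression(matrix(rng.normal(8, 1, (5, 3)), 1, 2))


class TestFilterDegs:
    def test_boundary_inclusive(self):
        rec = DEGRecord("P1", "G1", logfc=0.5, p=0.05)
        assert filter_degs([rec]) == [rec] and rec.passed

    def test_below_threshold_fails(self):
        assert filter_degs([DEGRecord("P1", "G1", logfc=0.49, p=0.001)]) == []
        assert filter_degs([DEGRecord("P1", "G1", logfc=2.0, p=0.051)]) == []

    def test_negative_logfc_passes_on_magnitude(self):
        assert len(filter_degs([DEGRecord("P1", "G1", -0.6, 0.01)])) == 1

    def test_empty_and_idempotent(self):
        assert filter_degs([]) == []
        recs = [DEGRecord(f"P{i}", "G", lfc, p) for i, (lfc, p) in
                enumerate([(0.6, 0.01), (0.1, 0.5), (1.0, 0.04)])]
        once = filter_degs(recs)
        assert filter_degs(once) == once


class TestCollapseProbes:
    def test_keeps_max_abs_logfc(self):
        recs = [DEGRecord("P1", "", 0.6, 0.01), DEGRecord("P2", "", -1.2, 0.2)]
        out = collapse_probes(recs, {"P1": "G1", "P2": "G1"})
        assert len(out) == 1
        assert out[0].logfc == -1.2 and out[0].gene_symbol == "G1"

    def test_identity_for_unique_probes(self):
        recs = [DEGRecord("P1", "", 0.5, 0.1), DEGRecord("P2", "", 0.2, 0.3)]
        out = collapse_probes(recs, {"P1": "G1", "P2": "G2"})
        assert {r.gene_symbol for r in out} == {"G1", "G2"}

    def test_unmapped_probe_excluded(self):
        recs = [DEGRecord("P1", "", 0.5, 0.1), DEGRecord("PX", "", 2.0, 0.01)]
        out = collapse_probes(recs, {"P1": "G1"})
        assert [r.gene_symbol for r in out] == ["G1"]

    def test_mean_mode(self):
        recs = [DEGRecord("P1", "", 1.0, 0.05), DEGRecord("P2", "", 0.0, 0.2)]
        out = collapse_probes(recs, {"P1": "G1", "P2": "G1"}, how="mean")
        assert out[0].logfc == pytest.approx(0.5)
        assert out[0].p == pytest.approx(0.05)


class TestUnions:
    def test_simple_union(self):
        assert union_deg_sets([{"A", "B"}, {"B", "C"}]) == {"A", "B", "C"}

    def test_printed_count_arithmetic(self):
        """Disjoint chips of 152 and 202 genes give 354; one shared gene
        gives 353."""
        chip1 = {f"A{i}" for i in range(152)}
        chip2 = {f"B{i}" for i in range(202)}
        assert len(union_deg_sets([chip1, chip2])) == 354
        chip2 = {"A0"} | {f"B{i}" for i in range(201)}
        assert len(union_deg_sets([chip1, chip2])) == 353

    def test_empty(self):
        assert union_deg_sets([]) == set()

    def test_disease_targets_case_folded(self, tmp_path):
        (tmp_path / "db.txt").write_text("A\nb\n")
        out = build_disease_targets({"a"}, [tmp_path / "db.txt"])
        assert out == {"A", "B"}

    def test_disease_targets_no_lists(self):
        assert build_disease_targets({"x", "Y"}) == {"X", "Y"}
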