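import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from pseudorank import (
    ConfigurationError,
    ExpressionMatrix,
    GPHyperParams,
    InvalidInputError,
    RunConfig,
    anova_gene_filter,
    center_data,
    mean_variance_filter,
    read_expression,
    read_samples,
    run_chain,
    write_expression,
    write_samples,
)
from pseudorank.cli import main as cli_main

from conftest import make_expr


class TestCentering:
    def test_constant_matrix_to_zero(self):
        expr = ExpressionMatrix(np.full((2, 3), 7.0), ["a", "b"], ["x", "y", "z"])
        assert np.allclose(center_data(expr).values, 0.0)

    def test_grand_mean_zero_and_variance_kept(self, rng):
        expr = make_expr(rng, n_genes=5, n_cells=9)
        centered = center_data(expr)
        assert abs(centered.values.mean()) < 1e-10
        assert centered.total_variance == pytest.approx(expr.total_variance)


class TestAnovaFilter:
    def _expr(self):
        # g0: strong capture-time signal; g1: identical group means with
        # within-group noise; g2: weak signal
        values = np.array(
            [
                [0.0, 0.2, -0.1, 5.0, 5.2, 4.9],
                [1.0, -1.0, 0.0, 1.0, -1.0, 0.0],
                [0.0, 0.5, -0.5, 0.6, 1.0, 0.2],
            ]
        )
        return ExpressionMatrix(
            values,
            ["strong", "flat", "weak"],
            [f"c{i}" for i in range(6)],
            capture_times=np.array([0, 0, 0, 1, 1, 1]),
        )

    def test_ranking_follows_manual_f_statistics(self):
        expr = self._expr()
        # manual one-way ANOVA per gene
        def f_stat(row):
            g1, g2 = row[:3], row[3:]
            grand = row.mean()
            ssb = 3 * ((g1.mean() - grand) ** 2 + (g2.mean() - grand) ** 2)
            ssw = ((g1 - g1.mean()) ** 2).sum() + ((g2 - g2.mean()) ** 2).sum()
            return (ssb / 1) / (ssw / 4)

        fs = np.array([f_stat(r) for r in expr.values])
        assert fs[0] > fs[2] > fs[1]
        kept = anova_gene_filter(expr, n_keep=1)
        assert kept.gene_ids == ["strong"]
        kept2 = anova_gene_filter(expr, n_keep=2)
        assert set(kept2.gene_ids) == {"strong", "weak"}

    def test_flat_gene_ranked_last(self):
        expr = self._expr()
        kept = anova_gene_filter(expr, n_keep=3)
        assert kept.n_genes == 3  # identity when n_keep = n_genes
        dropped = anova_gene_filter(expr, n_keep=2)
        assert "flat" not in dropped.gene_ids

    def test_p_threshold_mode(self):
        expr = self._expr()
        kept = anova_gene_filter(expr, p_threshold=1e-4)
        assert kept.gene_ids == ["strong"]

    def test_requires_capture_times(self, rng):
        expr = make_expr(rng, n_cells=6)
        with pytest.raises(InvalidInputError):
            anova_gene_filter(expr, n_keep=2)

    def test_requires_two_groups(self, rng):
        expr = make_expr(rng, n_cells=6, capture_blocks=(6,))
        with pytest.raises(InvalidInputError):
            anova_gene_filter(expr, n_keep=2)


class TestMeanVarianceFilter:
    def test_joint_high_beats_constant_zero(self, rng):
        values = np.vstack(
            [
                np.zeros(8),
                5.0 + 2.0 * rng.normal(size=8),
                0.1 * rng.normal(size=8),
            ]
        )
        expr = ExpressionMatrix(
            values, ["zero", "rich", "dull"], [f"c{i}" for i in range(8)]
        )
        kept = mean_variance_filter(expr, n_keep=1)
        assert kept.gene_ids == ["rich"]

    def test_identity_when_keeping_all(self, rng):
        expr = make_expr(rng, n_genes=4, n_cells=6)
        kept = mean_variance_filter(expr, n_keep=4)
        assert kept.gene_ids == expr.gene_ids

    def test_invariant_to_cell_order(self, rng):
        expr = make_expr(rng, n_genes=6, n_cells=10)
        shuffled = ExpressionMatrix(
            expr.values[:, ::-1], expr.gene_ids, expr.cell_ids[::-1]
        )
        assert (
            mean_variance_filter(expr, 3).gene_ids
            == mean_variance_filter(shuffled, 3).gene_ids
        )


class TestRoundTrips:
    @pytest.mark.parametrize("sep,suffix", [(",", "csv"), ("\t", "tsv")])
    def test_expression_roundtrip(self, rng, tmp_path, sep, suffix):
        expr = make_expr(rng, n_genes=4, n_cells=6)
        path = tmp_path / f"expr.{suffix}"
        write_expression(expr, path, sep=sep)
        back = read_expression(path)
        assert np.allclose(back.values, expr.values, atol=1e-12)
        assert back.gene_ids == expr.gene_ids
        assert back.cell_ids == expr.cell_ids

    def test_samples_roundtrip(self, rng, tmp_path):
        expr = make_expr(rng, n_cells=6)
        samples = run_chain(expr, 100, thin=10, seed=2)
        path = tmp_path / "chain.csv"
        write_samples(samples, path)
        back = read_samples(path)
        assert np.array_equal(back.orders, samples.orders)
        assert np.allclose(back.log_lik, samples.log_lik, atol=1e-12)
        assert np.allclose(back.log_sigma_w2, samples.log_sigma_w2, atol=1e-12)
        assert back.meta["seed"] == samples.meta["seed"]
        assert np.array_equal(back.move_proposed, samples.move_proposed)

    def test_positions_are_one_based_on_disk(self, rng, tmp_path):
        expr = make_expr(rng, n_cells=4)
        samples = run_chain(expr, 20, thin=10, seed=0)
        path = tmp_path / "chain.csv"
        write_samples(samples, path)
        df = pd.read_csv(path, comment="#")
        pos = df[[c for c in df.columns if c.startswith("pos_")]].to_numpy()
        assert pos.min() >= 1
        assert pos.max() <= 4


class TestRunConfig:
    def test_yaml_roundtrip(self, tmp_path):
        cfg = RunConfig(n_chains=5, mode="rank", active_moves=(3,))
        path = tmp_path / "config.yaml"
        cfg.to_yaml(path)
        back = RunConfig.from_yaml(path)
        assert back == cfg

    def test_unknown_keys_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown config keys"):
            RunConfig.from_dict({"n_chains": 2, "banana": 1})


class TestCLI:
    def test_end_to_end_workflow(self, tmp_path):
        runner = CliRunner()
        data = tmp_path / "data"
        out = tmp_path / "chains"
        r = runner.invoke(
            cli_main,
            ["simulate", "--preset", "sim2", "--seed", "1", "--out-dir", str(data)],
        )
        assert r.exit_code == 0, r.output
        r = runner.invoke(
            cli_main,
            [
                "run", "--expression", str(data / "expression.csv"),
                "--capture-times", str(data / "capture_times.csv"),
                "--out-dir", str(out), "--chains", "2", "--iterations", "400",
                "--thin", "10", "--seed", "3",
            ],
        )
        assert r.exit_code == 0, r.output
        assert (out / "chain_00.csv").exists()
        assert (out / "config.yaml").exists()
        r = runner.invoke(
            cli_main,
            [
                "converge", "--samples-dir", str(out),
                "--capture-times", str(data / "capture_times.csv"),
                "--reference", str(data / "truth.csv"),
            ],
        )
        # 40 thinned samples: the report must exist whether or not converged
        assert r.exit_code in (0, 3), r.output
        assert (out / "convergence.csv").exists()
        r = runner.invoke(
            cli_main,
            [
                "summarize", "--samples-dir", str(out),
                "--expression", str(data / "expression.csv"),
                "--capture-times", str(data / "capture_times.csv"),
            ],
        )
        assert r.exit_code == 0, r.output
        summary = pd.read_csv(out / "summary.csv")
        assert len(summary) == 90
        assert summary["sd_pseudotime"].min() >= 0

    def test_run_is_deterministic(self, tmp_path):
        runner = CliRunner()
        data = tmp_path / "data"
        runner.invoke(
            cli_main,
            ["simulate", "--preset", "sim1", "--seed", "2", "--out-dir", str(data)],
        )
        outs = []
        for name in ("a", "b"):
            out = tmp_path / name
            r = runner.invoke(
                cli_main,
                [
                    "run", "--expression", str(data / "expression.csv"),
                    "--out-dir", str(out), "--chains", "1",
                    "--iterations", "200", "--thin", "10", "--seed", "5",
                ],
            )
            assert r.exit_code == 0, r.output
            outs.append((out / "chain_00.csv").read_text())
        assert outs[0] == outs[1]

    def test_minicluster_subcommand(self, tmp_path):
        runner = CliRunner()
        data = tmp_path / "data"
        runner.invoke(
            cli_main,
            ["simulate", "--preset", "sim1", "--seed", "4", "--out-dir", str(data)],
        )
        out = tmp_path / "mc"
        r = runner.invoke(
            cli_main,
            [
                "minicluster", "--expression", str(data / "expression.csv"),
                "--capture-times", str(data / "capture_times.csv"),
                "--min-clusters", "2", "--out-dir", str(out),
            ],
        )
        assert r.exit_code == 0, r.output
        cmap = pd.read_csv(out / "minicluster_map.csv")
        assert len(cmap) == 90
        centroids = read_expression(out / "centroids.csv")
        # three capture times, 30 cells each, 1/8th rounded -> 4 clusters each
        assert centroids.n_cells == 12

    def test_malformed_expression_errors(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("gene_id,c1,c2\ng0,1.0\n")
        runner = CliRunner()
        r = runner.invoke(
            cli_main,
            ["run", "--expression", str(bad), "--out-dir", str(tmp_path / "o"),
             "--iterations", "10"],
        )
        assert r.exit_code != 0
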