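import numpy as np
import pandas as pd
import pytest

from rhizotrial.anova import (
    AnovaTable,
    BalanceError,
    FactorialAnova,
    GroupAnova,
    GroupModelSpec,
    MissingCellError,
    cell_means,
    fit_factorial_rcbd,
    fit_group_model,
    p_stars,
)
from rhizotrial.design import genotype_metadata_frame
from rhizotrial.simulate import jar_config, pot_config, simulate_trial


def _random_trial(g, s, r, seed, effects=True):
    """Small balanced RCBD table with arbitrary continuous response."""
    rng = np.random.default_rng(seed)
    rows = []
    a = rng.normal(0, 1, g) if effects else np.zeros(g)
    b = rng.normal(0, 1, s) if effects else np.zeros(s)
    for i in range(s):
        for j in range(g):
            for k in range(1, r + 1):
                rows.append(
                    {
                        "experiment": "jar",
                        "genotype": f"G{j}",
                        "treatment": f"S{i}",
                        "replicate": k,
                        "y": a[j] + b[i] + rng.normal(0, 0.5),
                    }
                )
    return pd.DataFrame(rows)


def _statsmodels_type1(df):
    """Independent sequential-SS oracle via explicit model fits."""
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    model = smf.ols(
        "y ~ C(replicate) + C(genotype) + C(treatment) + C(genotype):C(treatment)",
        data=df,
    ).fit()
    return anova_lm(model, typ=1)


class TestFactorialDf:
    def test_jar_df_structure(self, jar_anova):
        table = jar_anova.table_
        assert table["Genotype"].df == 9
        assert table["Strain"].df == 7
        assert table["Genotype x Strain"].df == 63
        assert table["Rep"].df == 4
        assert table["Residual"].df == 316
        assert table.total_df == 399  # g*s*r - 1

    def test_pot_subset_df_structure(self, pot_records):
        table = fit_factorial_rcbd(pot_records, response="sdw")
        assert table["Genotype"].df == 4
        assert table["Strain"].df == 5
        assert table["Genotype x Strain"].df == 20


def test_noiseless_additive_data_has_zero_interaction():
    cfg = jar_config(
        interaction_rank=0, singular_values=(), rep_effect_sd=0.0, noise_sd=1e-12
    )
    table = fit_factorial_rcbd(simulate_trial(cfg), response="sdw")
    assert table["Genotype x Strain"].ss == pytest.approx(0.0, abs=1e-9)
    assert table["Residual"].ss == pytest.approx(0.0, abs=1e-9)
    assert table["Genotype"].ss > 0.01
    assert table["Strain"].ss > 0.01


def test_ss_conservation(jar_anova, jar_records):
    """Source SS add up to the directly computed total SS."""
    y = jar_anova.cell_means_  # fitted on sdw of inoculated rows
    from rhizotrial.io import inoculated_only

    raw = inoculated_only(jar_records)["sdw"].to_numpy()
    total = ((raw - raw.mean()) ** 2).sum()
    assert jar_anova.table_.total_ss == pytest.approx(total, rel=1e-9)


@pytest.mark.parametrize("g,s,r", [(3, 3, 2), (4, 4, 3), (5, 6, 5)])
def test_closed_form_matches_model_comparison(g, s, r):
    df = _random_trial(g, s, r, seed=100 + g + s + r)
    ours = fit_factorial_rcbd(df, response="y")
    oracle = _statsmodels_type1(df)
    for source, name in [
        ("Rep", "C(replicate)"),
        ("Genotype", "C(genotype)"),
        ("Strain", "C(treatment)"),
        ("Genotype x Strain", "C(genotype):C(treatment)"),
        ("Residual", "Residual"),
    ]:
        assert ours[source].ss == pytest.approx(oracle.loc[name, "sum_sq"], rel=1e-8)
        assert ours[source].df == int(oracle.loc[name, "df"])


def test_row_order_invariance(jar_records):
    shuffled = jar_records.sample(frac=1.0, random_state=3)
    a = fit_factorial_rcbd(jar_records, response="sdw")
    b = fit_factorial_rcbd(shuffled, response="sdw")
    for source in a.sources:
        assert a[source].ss == pytest.approx(b[source].ss, rel=1e-12)


def test_df_partition():
    df = _random_trial(4, 3, 2, seed=1)
    table = fit_factorial_rcbd(df, response="y")
    g, s, r = 4, 3, 2
    assert [table[x].df for x in ("Genotype", "Strain", "Genotype x Strain", "Rep")] == [
        g - 1,
        s - 1,
        (g - 1) * (s - 1),
        r - 1,
    ]
    assert table.total_df == g * s * r - 1


class TestUnbalanced:
    def test_missing_plot_errors_by_default(self):
        df = _random_trial(3, 3, 2, seed=2).drop(index=0)
        with pytest.raises(BalanceError):
            fit_factorial_rcbd(df, response="y")

    def test_imputation_reduces_residual_df(self):
        df = _random_trial(3, 3, 3, seed=2)
        full = fit_factorial_rcbd(df, response="y")
        table = fit_factorial_rcbd(df.drop(index=0), response="y", unbalanced="impute")
        assert table["Residual"].df == full["Residual"].df - 1
        assert np.isfinite(table["Genotype x Strain"].f)

    def test_empty_cell_always_errors(self):
        df = _random_trial(3, 3, 2, seed=2)
        df = df[~((df["genotype"] == "G0") & (df["treatment"] == "S0"))]
        with pytest.raises(MissingCellError):
            fit_factorial_rcbd(df, response="y", unbalanced="impute")

    def test_single_replicate_f_undefined(self):
        df = _random_trial(3, 3, 1, seed=4)
        table = fit_factorial_rcbd(df, response="y")
        assert table["Residual"].df == 0
        assert table["Genotype x Strain"].f is None
        assert table["Genotype x Strain"].p is None


class TestGroupModel:
    def _meta_mapping(self, column):
        meta = genotype_metadata_frame()
        return dict(zip(meta["genotype"], meta[column]))

    def test_genepool_df(self, jar_records):
        spec = GroupModelSpec("genepool", self._meta_mapping("genepool"))
        table = fit_group_model(jar_records, spec, response="sdw")
        assert table["Group"].df == 1
        assert table["Genotype(Group)"].df == 8
        assert table["Group x Strain"].df == 7
        assert table["Genotype x Strain(Group)"].df == 56
        assert table["Strain"].df == 7

    def test_three_group_habit_df(self, jar_records):
        # three habit classes: merge the single IB genotype with B (bush types)
        mapping = self._meta_mapping("growth_habit")
        mapping = {g: ("B" if h == "IB" else h) for g, h in mapping.items()}
        table = fit_group_model(
            jar_records, GroupModelSpec("growth_habit", mapping), response="sdw"
        )
        assert table["Group"].df == 2

    def test_group_partition_identities(self, jar_records):
        spec = GroupModelSpec("genepool", self._meta_mapping("genepool"))
        grouped = fit_group_model(jar_records, spec, response="sdw")
        plain = fit_factorial_rcbd(jar_records, response="sdw")
        assert grouped["Group"].ss + grouped["Genotype(Group)"].ss == pytest.approx(
            plain["Genotype"].ss, rel=1e-9
        )
        assert grouped["Group x Strain"].ss + grouped[
            "Genotype x Strain(Group)"
        ].ss == pytest.approx(plain["Genotype x Strain"].ss, rel=1e-9)
        assert grouped.total_ss == pytest.approx(plain.total_ss, rel=1e-9)
        assert grouped.total_df == plain.total_df

    def test_error_terms_documented(self, jar_records):
        spec = GroupModelSpec("genepool", self._meta_mapping("genepool"))
        table = fit_group_model(jar_records, spec, response="sdw")
        assert table.error_term_map["Group"] == "Genotype(Group)"
        assert table.error_term_map["Group x Strain"] == "Genotype x Strain(Group)"

    def test_singleton_groups_untestable(self):
        df = _random_trial(2, 3, 2, seed=7)
        table = fit_group_model(
            df, GroupModelSpec("gp", {"G0": "A", "G1": "B"}), response="y"
        )
        assert table["Genotype(Group)"].df == 0
        assert table["Group"].f is None and table["Group"].p is None

    def test_unmapped_genotype_rejected(self, jar_records):
        with pytest.raises(KeyError):
            fit_group_model(
                jar_records, GroupModelSpec("gp", {"G764": "A", "G1372": "B"}), "sdw"
            )

    def test_group_null_type1_rate(self):
        """With genotype effects drawn iid regardless of group, the Group
        F-test against Genotype(Group) holds its nominal 5% level."""
        from rhizotrial.design import jar_design

        design = jar_design(replicates=3)
        groups = {g: ("A" if i < 5 else "B") for i, g in enumerate(design.genotypes)}
        rng = np.random.default_rng(88)
        rejections = 0
        n_runs = 500
        for run in range(n_runs):
            eff = rng.normal(0, 0.3, design.n_genotypes)
            eff -= eff.mean()
            cfg = jar_config(
                design=design,
                seed=int(rng.integers(2**31)),
                genotype_effects=dict(zip(design.genotypes, eff)),
                interaction_rank=0,
                singular_values=(),
            )
            table = fit_group_model(
                simulate_trial(cfg), GroupModelSpec("gp", groups), response="sdw"
            )
            rejections += table["Group"].p < 0.05
        assert 0.03 <= rejections / n_runs <= 0.07


class TestCellMeans:
    def test_constant_response(self):
        df = _random_trial(3, 2, 2, seed=0)
        df["y"] = 3.25
        mat = cell_means(df, "y")
        assert (mat.values == pytest.approx(3.25)) and mat.shape == (2, 3)

    def test_single_replicate_identity(self):
        df = _random_trial(3, 2, 1, seed=1)
        mat = cell_means(df, "y")
        for row in df.itertuples(index=False):
            assert mat.loc[row.treatment, row.genotype] == pytest.approx(row.y)

    def test_matches_brute_force(self):
        df = _random_trial(3, 3, 2, seed=9)
        mat = cell_means(df, "y")
        for strain in mat.index:
            for genotype in mat.columns:
                sub = df[(df["treatment"] == strain) & (df["genotype"] == genotype)]
                assert mat.loc[strain, genotype] == pytest.approx(sub["y"].mean())

    def test_empty_cell_named(self):
        df = _random_trial(3, 2, 2, seed=9)
        df = df[~((df["genotype"] == "G1") & (df["treatment"] == "S0"))]
        with pytest.raises(MissingCellError, match="G1"):
            cell_means(df, "y")


@pytest.mark.parametrize(
    "p,stars",
    [(0.0005, "***"), (0.004, "**"), (0.03, "*"), (0.07, "."), (0.5, ""), (None, "")],
)
def test_p_stars(p, stars):
    assert p_stars(p) == stars
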