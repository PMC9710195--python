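"""Predicted directions, concordance scores and their control nulls."""

import numpy as np
import pandas as pd
import pytest

from clineseas.errors import ConfigError
from clineseas import directionality
from clineseas.directionality import (
    concordance_crosspop,
    concordance_pairwise,
    direction_records,
    gene_concordance,
    predicted_sign,
)
from clineseas.matched_controls import build_control_sets
from clineseas.synthetic_data import SimConfig, simulate_dataset
from clineseas.tables_io import DeGeneSet


class TestPredictedSign:
    def test_upregulating_allele_of_northern_gene_expected_north(self):
        assert predicted_sign(+1, +1, "latitudinal", "clinal") == +1

    def test_heat_shock_gene_expected_less_common_in_spring(self):
        assert predicted_sign(+1, +1, "heat_shock", "seasonal") == -1

    def test_downregulating_allele_of_starvation_gene(self):
        assert predicted_sign(-1, +1, "starvation", "clinal") == -1

    @pytest.mark.parametrize("label,clinal,seasonal", [
        ("latitudinal", +1, +1),
        ("chill_coma", +1, +1),
        ("starvation", +1, +1),
        ("low_temp", +1, +1),
        ("heat_shock", -1, -1),
        ("high_temp", -1, -1),
    ])
    def test_axis_hypotheses(self, label, clinal, seasonal):
        assert predicted_sign(+1, +1, label, "clinal") == clinal
        assert predicted_sign(+1, +1, label, "seasonal") == seasonal

    def test_unknown_label_rejected(self):
        with pytest.raises(ConfigError):
            predicted_sign(+1, +1, "diapause", "clinal")


def brute_force_score(pi, omega):
    num = den = 0
    for p, o in zip(pi, omega):
        if o == 0:
            continue
        den += 1
        if p * o == 1:
            num += 1
    return num / den if den else float("nan")


def _de_set_over(eqtls, label="latitudinal", sign=+1):
    return DeGeneSet(label, {g: sign for g in eqtls["gene_id"].unique()})


class TestCrosspopConcordance:
    def test_perfectly_concordant_set_scores_one(self, toy_panel, toy_controls):
        snps, eqtls, _ = toy_panel
        snps = snps.copy()
        # align every beta sign with the predicted direction
        de = _de_set_over(eqtls)
        recs = direction_records(eqtls, de, "clinal", sex_classes=("female", "male", "non_sex_biased"))
        pi_of = dict(zip(recs["snp_id"], recs["pi"]))
        snps["clinal_beta"] = [
            abs(b) * pi_of.get(s, 1)
            for s, b in zip(snps["snp_id"], snps["clinal_beta"])
        ]
        res = concordance_crosspop(
            snps, eqtls, de, toy_controls, "clinal",
            sex_classes=("female", "male", "non_sex_biased"),
        )
        assert res.score == 1.0

    def test_score_matches_brute_force(self, toy_panel, toy_controls):
        snps, eqtls, _ = toy_panel
        de = _de_set_over(eqtls)
        sex = ("female", "male", "non_sex_biased")
        res = concordance_crosspop(snps, eqtls, de, toy_controls, "clinal", sex_classes=sex)
        recs = direction_records(eqtls, de, "clinal", sex_classes=sex)
        beta = dict(zip(snps["snp_id"], np.sign(snps["clinal_beta"])))
        expected = brute_force_score(
            recs["pi"].tolist(), [beta[s] for s in recs["snp_id"]]
        )
        assert res.score == pytest.approx(expected)
        assert res.n_eqtls == len(recs)

    def test_null_scores_match_brute_force(self, toy_panel, toy_controls):
        snps, eqtls, _ = toy_panel
        cs = toy_controls
        de = _de_set_over(eqtls)
        sex = ("female", "male", "non_sex_biased")
        res = concordance_crosspop(snps, eqtls, de, cs, "clinal", sex_classes=sex)
        recs = direction_records(eqtls, de, "clinal", sex_classes=sex)
        beta = dict(zip(snps["snp_id"], np.sign(snps["clinal_beta"])))
        ids = snps["snp_id"].to_numpy()
        rows = cs.rows_for(recs["snp_id"].to_numpy(dtype=object))
        for k in range(cs.n_sets):
            omegas = [beta[ids[cs.control_idx[r, k]]] for r in rows]
            assert res.null_scores[k] == pytest.approx(
                brute_force_score(recs["pi"].tolist(), omegas)
            )

    def test_sign_flip_symmetry(self, toy_panel, toy_controls):
        """Negating every observed sign maps the score to 1 - score."""
        snps, eqtls, _ = toy_panel
        de = _de_set_over(eqtls)
        sex = ("female", "male", "non_sex_biased")
        a = concordance_crosspop(snps, eqtls, de, toy_controls, "clinal", sex_classes=sex)
        flipped = snps.copy()
        flipped["clinal_beta"] = -flipped["clinal_beta"]
        b = concordance_crosspop(flipped, eqtls, de, toy_controls, "clinal", sex_classes=sex)
        assert a.score + b.score == pytest.approx(1.0)

    def test_empty_overlap_not_testable(self, toy_panel, toy_controls):
        snps, eqtls, _ = toy_panel
        de = DeGeneSet("latitudinal", {"absent_gene": 1})
        res = concordance_crosspop(snps, eqtls, de, toy_controls, "clinal")
        assert not res.testable and res.verdict == "neutral"

    def test_verdict_trichotomy(self, small_sim):
        data, cs = small_sim
        for label, de in data.de_sets.items():
            for model in ("clinal", "seasonal"):
                res = concordance_crosspop(
                    data.snps, data.eqtls, de, cs, model, bonferroni_m=23
                )
                assert res.verdict in directionality.VERDICTS
                if res.testable and res.verdict == "concordant":
                    assert res.score > 0.5 and res.emp_p <= res.adjusted_alpha


class TestPairwiseConcordance:
    def test_identical_samples_not_testable(self, toy_panel, toy_controls):
        snps, eqtls, _ = toy_panel
        snps = snps.copy()
        snps["freq_FL"] = 0.4
        snps["freq_ME"] = 0.4
        design = pd.DataFrame(
            {
                "sample_id": ["FL", "ME"],
                "locality": ["FL", "ME"],
                "role": "clinal",
                "latitude": [25.5, 44.8],
                "pair_id": [None, None],
            }
        )
        de = _de_set_over(eqtls)
        res = concordance_pairwise(
            snps, eqtls, de, toy_controls, "fl_me", design,
            sex_classes=("female", "male", "non_sex_biased"),
        )
        assert not res.testable

    def test_noiseless_fully_concordant_localities_score_one(self):
        cfg = SimConfig(
            seed=21, n_snps_per_arm=2000, n_genes=180, eqtls_per_gene=2.0,
            n_pairs=3, noise_sd=0.0, concordance_rate=1.0,
            de_set_sizes={"latitudinal": 180},
        )
        data = simulate_dataset(cfg)
        cs = build_control_sets(data.snps, list(cfg.inversions), n_sets=20, seed=21)
        de = data.de_sets["latitudinal"]
        sex = ("female", "male", "non_sex_biased")
        for pair in ("loc01", "loc02", "loc03"):
            res = concordance_pairwise(
                data.snps, data.eqtls, de, cs, f"locality:{pair}",
                data.design, sex_classes=sex,
            )
            assert res.score == 1.0

    def test_unknown_comparison_rejected(self, toy_panel, toy_controls):
        snps, eqtls, _ = toy_panel
        design = pd.DataFrame(
            {"sample_id": [], "locality": [], "role": [], "latitude": [],
             "pair_id": []}
        )
        with pytest.raises(ConfigError):
            concordance_pairwise(
                snps, eqtls, _de_set_over(eqtls), toy_controls,
                "locality:nowhere", design,
            )

    def test_locality_scores_scatter_binomially_under_null(self):
        """With no seasonal effect, each locality's spring-fall signs are
        independent fair coins, so per-locality scores center on 0.5 with
        binomial spread."""
        cfg = SimConfig(
            seed=33, n_snps_per_arm=2500, n_genes=180, eqtls_per_gene=3.0,
            n_pairs=8, noise_sd=0.05, beta_scale_seasonal=0.0,
            concordance_rate=0.5, de_set_sizes={"latitudinal": 180},
        )
        data = simulate_dataset(cfg)
        cs = build_control_sets(data.snps, list(cfg.inversions), n_sets=10, seed=33)
        sex = ("female", "male", "non_sex_biased")
        scores, ns = [], []
        for i in range(1, 9):
            res = concordance_pairwise(
                data.snps, data.eqtls, data.de_sets["latitudinal"], cs,
                f"locality:loc{i:02d}", data.design, sex_classes=sex,
            )
            scores.append(res.score)
            ns.append(res.n_eqtls)
        mean_n = np.mean(ns)
        se = np.sqrt(0.25 / mean_n)
        assert abs(np.mean(scores) - 0.5) < 3 * se / np.sqrt(len(scores))
        assert 0.2 * se < np.std(scores) < 2.5 * se


class TestKappaRecovery:
    @pytest.mark.parametrize("kappa", [0.6, 0.8])
    def test_crosspop_score_recovers_injected_concordance_rate(self, kappa):
        """At ~2000 scored eQTLs the cross-population score estimates the
        injected concordance rate to within 0.03."""
        cfg = SimConfig(
            seed=int(kappa * 100), n_snps_per_arm=12_500, n_genes=400,
            eqtls_per_gene=5.0, concordance_rate=kappa,
            de_set_sizes={"latitudinal": 400}, n_pairs=1,
        )
        data = simulate_dataset(cfg, with_freqs=False)
        cs = build_control_sets(data.snps, list(cfg.inversions), n_sets=50,
                                seed=cfg.seed)
        res = concordance_crosspop(
            data.snps, data.eqtls, data.de_sets["latitudinal"], cs, "clinal",
            sex_classes=("female", "male", "non_sex_biased"),
        )
        assert res.n_eqtls >= 1900
        assert abs(res.score - kappa) <= 0.03


class TestGeneConcordance:
    def test_gene_scores_one_when_all_its_eqtls_concordant(self, toy_panel, toy_controls):
        snps, eqtls, _ = toy_panel
        snps = snps.copy()
        gene = eqtls["gene_id"].iloc[0]
        de = DeGeneSet("latitudinal", {gene: 1})
        # align every eQTL of the gene with its predicted direction
        for r in eqtls[eqtls["gene_id"] == gene].itertuples():
            snps.loc[snps["snp_id"] == r.snp_id, "clinal_beta"] = 0.02 * r.effect_sign
        df = gene_concordance(
            snps, eqtls, de, toy_controls, "clinal",
            sex_classes=("female", "male", "non_sex_biased"),
        )
        row = df[df["n_eqtls"] > 0].iloc[0]
        assert row["score"] == 1.0

    def test_dominant_gene_weighted_average(self):
        """A gene holding 60% of records at per-gene rate 0.9 against a 0.5
        background pools to ~0.74 and raises the dominance flag."""
        cfg = SimConfig(
            seed=55, n_snps_per_arm=3000, n_genes=180, eqtls_per_gene=2.0,
            n_pairs=1, concordance_rate=0.5, de_set_sizes={"latitudinal": 20},
        )
        data = simulate_dataset(cfg)
        snps, eqtls = data.snps.copy(), data.eqtls
        de = data.de_sets["latitudinal"]
        sex = ("female", "male", "non_sex_biased")
        recs = direction_records(eqtls, de, "clinal", sex_classes=sex)
        # make one member gene dominant: replicate its records via a
        # direct construction of the expected pooled score
        counts = recs.groupby("gene_id").size()
        dom_gene = counts.idxmax()
        # force the dominant gene's omegas to match pi at rate ~0.9 and
        # the others at ~0.5 exactly by construction
        rng = np.random.default_rng(0)
        beta = dict(zip(snps["snp_id"], np.abs(snps["clinal_beta"])))
        new_beta = dict(zip(snps["snp_id"], snps["clinal_beta"]))
        for r in recs.itertuples():
            rate = 0.9 if r.gene_id == dom_gene else 0.5
            sgn = r.pi if rng.random() < rate else -r.pi
            new_beta[r.snp_id] = sgn * beta[r.snp_id]
        snps["clinal_beta"] = snps["snp_id"].map(new_beta)
        cs = build_control_sets(snps, list(cfg.inversions), n_sets=10, seed=55)
        df = gene_concordance(snps, eqtls, de, cs, "clinal", sex_classes=sex,
                              dominance_fraction=0.2)
        scored = df[df["n_eqtls"] > 0]
        pooled = (scored["score"] * scored["n_eqtls"]).sum() / scored["n_eqtls"].sum()
        w_dom = scored.set_index("gene_id").loc[dom_gene, "n_eqtls"] / scored["n_eqtls"].sum()
        expected = w_dom * scored.set_index("gene_id").loc[dom_gene, "score"] + (
            1 - w_dom
        ) * (
            (scored[scored["gene_id"] != dom_gene]["score"]
             * scored[scored["gene_id"] != dom_gene]["n_eqtls"]).sum()
            / scored[scored["gene_id"] != dom_gene]["n_eqtls"].sum()
        )
        assert pooled == pytest.approx(expected)
        if w_dom > 0.2:
            assert df.set_index("gene_id").loc[dom_gene, "dominant"]

    def test_pooled_equals_weighted_mean_of_genes(self, small_sim):
        data, cs = small_sim
        de = data.de_sets["latitudinal"]
        df = gene_concordance(data.snps, data.eqtls, de, cs, "clinal")
        scored = df[df["n_eqtls"] > 0]
        pooled = (scored["score"] * scored["n_eqtls"]).sum() / scored["n_eqtls"].sum()
        res = concordance_crosspop(data.snps, data.eqtls, de, cs, "clinal")
        assert pooled == pytest.approx(res.score)
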