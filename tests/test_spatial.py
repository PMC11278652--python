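"""Geodetic distances, Bray–Curtis, Mantel, distance decay, env drivers, db-RDA."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import binom

import riverweb as rw
from riverweb.errors import ValidationError
from riverweb.spatial import DistanceMatrix
from riverweb.tables import SampleMetadata


def _meta(lat, lon, season="spring"):
    n = len(lat)
    df = pd.DataFrame({
        "site_no": range(1, n + 1), "season": season,
        "latitude": lat, "longitude": lon, "elevation": 0.0,
        "landform": "plain", "region": "non-source",
    }, index=[f"s{i}" for i in range(n)])
    return SampleMetadata(df)


def _dm(points, metric="geodetic-km"):
    pts = np.asarray(points, dtype=float)
    return DistanceMatrix(
        tuple(f"s{i}" for i in range(len(pts))),
        squareform(pdist(pts)), metric,
    )


class TestGeodetic:
    def test_identical_coordinates_zero(self):
        geo = rw.geodetic_distance_matrix(_meta([30.0, 30.0], [110.0, 110.0]))
        assert geo.values[0, 1] == 0.0

    def test_antipodal_half_circumference(self):
        geo = rw.geodetic_distance_matrix(_meta([0.0, 0.0], [0.0, 180.0]))
        assert geo.values[0, 1] == pytest.approx(np.pi * 6371.0088, rel=1e-6)

    def test_symmetric_zero_diagonal(self):
        geo = rw.geodetic_distance_matrix(
            _meta([30.0, 31.0, 32.5], [110.0, 112.0, 115.0])
        )
        assert np.allclose(geo.values, geo.values.T)
        assert np.all(np.diag(geo.values) == 0)

    def test_missing_coordinate_lists_samples(self):
        meta = _meta([30.0, np.nan], [110.0, 111.0])
        with pytest.raises(ValidationError, match="s1"):
            rw.geodetic_distance_matrix(meta)


class TestBrayCurtis:
    def test_formula_cases(self):
        df = pd.DataFrame([[1.0, 0.0], [0.0, 1.0], [2.0, 2.0], [1.0, 1.0]],
                          index=list("abcd"))
        d = rw.bray_curtis_matrix(df)
        sq = pd.DataFrame(d.values, index=d.ids, columns=d.ids)
        assert sq.loc["a", "b"] == pytest.approx(1.0)  # disjoint supports
        assert sq.loc["c", "d"] == pytest.approx(1 / 3)  # (|1|+|1|)/(3+3)
        assert sq.loc["c", "c"] == 0.0

    def test_negative_features_need_scaling(self):
        df = pd.DataFrame([[1.0, -0.5], [0.2, 0.3]])
        with pytest.raises(ValidationError):
            rw.bray_curtis_matrix(df)
        scaled = rw.bray_curtis_matrix(df, scale_features=True)
        assert np.all(scaled.values >= 0)

    def test_all_zero_pair_warns_and_is_zero(self):
        df = pd.DataFrame([[0.0, 0.0], [0.0, 0.0], [1.0, 2.0]])
        with pytest.warns(UserWarning):
            d = rw.bray_curtis_matrix(df)
        assert d.values[0, 1] == 0.0


class TestMantel:
    def test_identity_gives_r1_minimal_p(self):
        rng = np.random.default_rng(0)
        d = _dm(rng.random((12, 2)))
        res = rw.mantel_test(d, d, n_permutations=999, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 1000)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        d = _dm(rng.random((10, 2)))
        d2 = DistanceMatrix(d.ids, np.sqrt(d.values), d.metric)
        res = rw.mantel_test(d, d2, n_permutations=99, seed=2)
        assert res.r == pytest.approx(1.0)

    def test_matches_skbio_statistic(self):
        """Cross-check the Spearman Mantel r against the scikit-bio oracle."""
        from skbio.stats.distance import DistanceMatrix as SkbioDM, mantel
        rng = np.random.default_rng(3)
        a = _dm(rng.random((15, 2)))
        b = _dm(rng.random((15, 2)))
        ours = rw.mantel_test(a, b, n_permutations=99, seed=0)
        theirs, _, _ = mantel(
            SkbioDM(a.values, ids=a.ids), SkbioDM(b.values, ids=b.ids),
            method="spearman", permutations=0,
        )
        assert ours.r == pytest.approx(float(theirs), abs=1e-10)

    def test_type_one_error_calibrated(self):
        """Independent matrices: rejection rate at alpha=0.05 stays inside the
        95% binomial interval over 50 null replicates."""
        rng = np.random.default_rng(4)
        rejections = 0
        n_rep = 50
        for _ in range(n_rep):
            a = _dm(rng.random((15, 2)))
            b = _dm(rng.random((15, 2)))
            res = rw.mantel_test(a, b, n_permutations=199,
                                 seed=int(rng.integers(2**31)))
            rejections += res.p <= 0.05
        lo, hi = binom.interval(0.95, n_rep, 0.05)
        assert lo <= rejections <= hi

    def test_mismatched_ids_rejected(self):
        a = _dm(np.random.default_rng(5).random((6, 2)))
        b = DistanceMatrix(tuple(f"x{i}" for i in range(6)), a.values, a.metric)
        with pytest.raises(ValidationError):
            rw.mantel_test(a, b)


class TestDistanceDecay:
    def _community_pair(self, decay_length, seed=7):
        # study-scale single-season slice: 59 sites along the river
        spec = rw.CommunitySpec(
            n_otus=100, n_sites=59, seasons=("spring",),
            module_spec=[(25, 0.95)] * 3, zero_inflation=0.0,
            decay_length=decay_length, seed=seed,
        )
        ds = rw.generate_dataset(spec)
        geo = rw.geodetic_distance_matrix(ds.metadata)
        bc = rw.bray_curtis_matrix(ds.table.data)
        return geo, bc

    def test_constant_similarity_zero_slope(self):
        ids = tuple(f"s{i}" for i in range(6))
        rng = np.random.default_rng(8)
        geo = _dm(rng.random((6, 2)))
        const = DistanceMatrix(ids, 0.4 * (1 - np.eye(6)), "bray-curtis")
        slope, _, mantel = rw.distance_decay_fit(geo, const, n_permutations=9, seed=0)
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert mantel is None

    def test_doubling_distances_halves_slope(self):
        geo, bc = self._community_pair(1000.0)
        s1, _, _ = rw.distance_decay_fit(geo, bc, n_permutations=9, seed=0)
        geo2 = DistanceMatrix(geo.ids, 2 * geo.values, geo.metric)
        s2, _, _ = rw.distance_decay_fit(geo2, bc, n_permutations=9, seed=0)
        assert s2 == pytest.approx(s1 / 2)

    def test_spatial_structure_gives_negative_significant_slope(self):
        """At the default 1000-km decay scale the community similarity falls
        with distance: slope < 0 with a significant Mantel correlation."""
        geo, bc = self._community_pair(1000.0)
        slope, _, mantel = rw.distance_decay_fit(geo, bc, n_permutations=199, seed=1)
        assert slope < 0
        assert mantel.p <= 0.05

    def test_decay_length_orders_slope_within_resolved_regime(self):
        """Stronger spatial autocorrelation (shorter decay within the range
        the site spacing can resolve) steepens the distance-decay curve."""
        geo_s, bc_s = self._community_pair(2000.0)
        geo_l, bc_l = self._community_pair(20000.0)
        s_short, _, _ = rw.distance_decay_fit(geo_s, bc_s, n_permutations=9, seed=0)
        s_long, _, _ = rw.distance_decay_fit(geo_l, bc_l, n_permutations=9, seed=0)
        assert abs(s_short) > abs(s_long)


class TestEnvCorrelations:
    def test_identity_response_rho_one(self):
        rng = np.random.default_rng(10)
        env = pd.DataFrame({"WT": rng.normal(15, 3, 20)},
                           index=[f"s{i}" for i in range(20)])
        responses = pd.DataFrame({"module_0": env["WT"]})
        out = rw.env_network_correlations(env, responses)
        assert out.loc[0, "rho"] == pytest.approx(1.0)

    def test_constant_factor_missing(self):
        env = pd.DataFrame({"pH": np.full(10, 8.0)},
                           index=[f"s{i}" for i in range(10)])
        responses = pd.DataFrame({"m": np.arange(10.0)}, index=env.index)
        out = rw.env_network_correlations(env, responses)
        assert np.isnan(out.loc[0, "rho"])

    def test_null_significant_fraction_near_alpha(self):
        rng = np.random.default_rng(11)
        fracs = []
        for _ in range(20):
            idx = [f"s{i}" for i in range(30)]
            env = pd.DataFrame(rng.normal(size=(30, 4)),
                               columns=list("wxyz"), index=idx)
            resp = pd.DataFrame(rng.normal(size=(30, 5)),
                                columns=[f"m{i}" for i in range(5)], index=idx)
            out = rw.env_network_correlations(env, resp)
            fracs.append(rw.significant_fraction(out, 0.05, use_adjusted=False))
        assert np.mean(fracs) == pytest.approx(0.05, abs=0.04)

    def test_module_abundance_is_member_sum(self, recovery_network, recovery_dataset):
        ds = recovery_dataset
        ma = rw.module_total_abundance(recovery_network, ds.table)
        mid = recovery_network.nodes[next(iter(recovery_network.nodes))]["module"]
        members = [n for n in recovery_network
                   if recovery_network.nodes[n]["module"] == mid]
        np.testing.assert_allclose(
            ma[f"module_{mid}"].to_numpy(),
            ds.table.data[members].sum(axis=1).to_numpy(),
        )


class TestDbRda:
    def _env(self, n, seed, extra=None):
        rng = np.random.default_rng(seed)
        idx = [f"s{i}" for i in range(n)]
        env = pd.DataFrame({
            "WT": rng.normal(15, 4, n),
            "pH": rng.normal(8, 0.3, n),
            "noise": rng.normal(0, 1, n),
        }, index=idx)
        if extra is not None:
            env["grad"] = extra
        return env

    def _community_driven_by(self, driver, n_otus=40, seed=0):
        """Half the OTUs respond log-linearly to the driver."""
        rng = np.random.default_rng(seed)
        n = len(driver)
        base = rng.normal(0, 1, n_otus)
        z = rng.normal(0, 1, (n, n_otus))
        load = np.zeros(n_otus)
        load[: n_otus // 2] = 2.0
        logab = base + z + np.outer(
            (driver - np.mean(driver)) / np.std(driver), load
        )
        ab = np.exp(logab)
        ab /= ab.sum(axis=1, keepdims=True)
        return rw.OtuTable(pd.DataFrame(
            ab, index=[f"s{i}" for i in range(n)],
            columns=[f"OTU{j}" for j in range(n_otus)],
        ))

    def test_constructed_gradient_identified(self):
        rng = np.random.default_rng(12)
        grad = rng.normal(0, 1, 30)
        env = self._env(30, 13, extra=grad)
        comm = self._community_driven_by(grad, seed=14)
        res = rw.db_rda(comm, env, n_permutations=199, seed=0)
        assert res.factors["adj_r_squared"].idxmax() == "grad"
        assert res.factors.loc["grad", "p"] <= 0.005
        assert np.all(res.axis_pct >= 0) and np.all(res.axis_pct <= 100)

    def test_noise_factor_adjusted_r2_near_zero(self):
        rng = np.random.default_rng(15)
        adjs = []
        for seed in range(5):
            grad = rng.normal(0, 1, 25)
            env = self._env(25, 100 + seed, extra=grad)
            comm = self._community_driven_by(grad, seed=200 + seed)
            res = rw.db_rda(comm, env, n_permutations=99, seed=seed)
            adjs.append(res.factors.loc["noise", "adj_r_squared"])
        assert np.mean(adjs) == pytest.approx(0.0, abs=0.02)

    def test_relabelling_invariance(self):
        rng = np.random.default_rng(16)
        grad = rng.normal(0, 1, 20)
        env = self._env(20, 17, extra=grad)
        comm = self._community_driven_by(grad, seed=18)
        res = rw.db_rda(comm, env, n_permutations=49, seed=3)
        perm = rng.permutation(20)
        comm2 = rw.OtuTable(comm.data.iloc[perm])
        env2 = env.iloc[perm]
        res2 = rw.db_rda(comm2, env2, n_permutations=49, seed=3)
        np.testing.assert_allclose(res2.axis_pct, res.axis_pct, atol=1e-8)
        np.testing.assert_allclose(
            res2.factors["r_squared"], res.factors["r_squared"], atol=1e-8
        )

    def test_collinear_factors_rejected(self):
        rng = np.random.default_rng(19)
        env = self._env(20, 20)
        env["WT2"] = env["WT"] * 2.0
        comm = self._community_driven_by(rng.normal(0, 1, 20), seed=21)
        with pytest.raises(ValidationError, match="collinear"):
            rw.db_rda(comm, env, n_permutations=9, seed=0)

    def test_single_constraint_matches_pcoa_regression_oracle(self):
        """R² of a 2-factor-less model equals regressing the Bray–Curtis PCoA
        coordinates (scikit-bio) on the same constraint directly."""
        from skbio.stats.ordination import pcoa
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        rng = np.random.default_rng(22)
        grad = rng.normal(0, 1, 10)
        comm = self._community_driven_by(grad, n_otus=20, seed=23)
        env = pd.DataFrame({
            "grad": grad, "other": rng.normal(0, 1, 10)
        }, index=comm.data.index)
        res = rw.db_rda(comm, env, n_permutations=9, seed=0)

        d = squareform(pdist(comm.values, metric="braycurtis"))
        ord_ = pcoa(SkbioDM(d, ids=list(comm.data.index)))
        coords = ord_.samples.to_numpy()
        eigs = ord_.eigvals.to_numpy()
        coords = coords[:, eigs > 1e-10]
        x = (grad - grad.mean()) / grad.std(ddof=1)
        xd = np.column_stack([np.ones(10), x])
        beta, *_ = np.linalg.lstsq(xd, coords, rcond=None)
        fitted = xd @ beta
        fitted -= fitted.mean(axis=0)
        centered = coords - coords.mean(axis=0)
        oracle_r2 = (fitted ** 2).sum() / (centered ** 2).sum()
        assert res.factors.loc["grad", "r_squared"] == pytest.approx(
            oracle_r2, abs=1e-6
        )
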