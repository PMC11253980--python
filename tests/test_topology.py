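"""Soma packing, dendritic sampling, axon growth, synapse formation."""

import numpy as np
import pytest
from scipy.spatial import cKDTree
from scipy.stats import truncnorm

from neuroslice.morphology import GENOTYPES, GenotypeParams, WT_CONSTANTS
from neuroslice.topology import (
    TopologyConfig, place_somas, sample_dendrite_radii, grow_axon,
    establish_synapses, establish_synapses_bruteforce, generate_network,
    scp_table, save_network, load_network, save_geometry, SynapticNetwork)
from neuroslice._kernels import scp_lookup
from neuroslice.metrics import network_density


class TestConfig:
    def test_packing_feasibility_checked(self):
        with pytest.raises(ValueError):
            TopologyConfig(N=2, L=100.0, soma_radius=49.0, dend_mean=60.0)

    def test_grid_must_divide_domain(self):
        with pytest.raises(ValueError):
            TopologyConfig(L=1500.0, grid_resolution=7.0)


class TestPlaceSomas:
    def test_single_point(self):
        cfg = TopologyConfig(N=1, L=100.0, dend_mean=20.0)
        p = place_somas(cfg, np.random.default_rng(0))
        assert p.shape == (1, 2)
        assert np.all((p >= 0) & (p < 100.0))

    def test_full_scale_min_distance_kdtree(self):
        cfg = TopologyConfig()
        pos = place_somas(cfg, np.random.default_rng(123))
        tree = cKDTree(pos, boxsize=cfg.L)   # periodic KD-tree oracle
        d, _ = tree.query(pos, k=2)
        assert d[:, 1].min() >= 2 * cfg.soma_radius - 1e-9

    def test_infeasible_packing_raises(self):
        cfg = TopologyConfig(N=40, L=100.0, soma_radius=8.0, dend_mean=20.0,
                             max_rejections=20000)
        # 40 disks of r=8 cannot pack a 100x100 torus at min distance 16
        with pytest.raises(RuntimeError):
            place_somas(cfg, np.random.default_rng(0))


class TestDendriteRadii:
    def test_zero_spread(self):
        cfg = TopologyConfig(N=10, dend_sd=0.0)
        assert np.all(sample_dendrite_radii(cfg, np.random.default_rng(0))
                      == cfg.dend_mean)

    def test_truncated_mean_matches_closed_form(self):
        cfg = TopologyConfig(N=10)
        r = sample_dendrite_radii(cfg, np.random.default_rng(7), n=100_000)
        a = (cfg.soma_radius - cfg.dend_mean) / cfg.dend_sd
        expected = truncnorm.mean(a, np.inf, loc=cfg.dend_mean,
                                  scale=cfg.dend_sd)
        assert expected == pytest.approx(156.5, abs=0.5)
        assert abs(r.mean() - expected) < 1.0

    def test_truncation_contract(self):
        cfg = TopologyConfig(N=10, dend_mean=100.66)
        r = sample_dendrite_radii(cfg, np.random.default_rng(1), n=100_000)
        assert r.min() > cfg.soma_radius


class TestGrowAxon:
    def test_straight_ray_when_angle_sd_zero(self):
        cfg = TopologyConfig(N=10, axon_angle_sd=0.0)
        rng = np.random.default_rng(3)
        path = grow_axon(np.array([750.0, 750.0]), cfg, rng)
        # all cells lie on one line through the start
        v = path - path[0]
        cross = v[:, 0] * v[-1, 1] - v[:, 1] * v[-1, 0]
        assert np.all(np.abs(cross) <= np.abs(v[-1]).max() * 1.0)

    def test_rayleigh_total_length(self):
        cfg = TopologyConfig(N=10)
        rng = np.random.default_rng(11)
        sigma = cfg.axon_mean_length / np.sqrt(np.pi / 2)
        lengths = rng.rayleigh(sigma, 100_000)
        se = lengths.std() / np.sqrt(len(lengths))
        assert abs(lengths.mean() - 500.0) < 3 * se + 1.5

    def test_path_cell_count_tracks_length(self):
        # one cell per μm of arc length (consecutive duplicates removed)
        cfg = TopologyConfig(N=10, axon_angle_sd=0.0)
        rng = np.random.default_rng(5)
        path = grow_axon(np.array([10.0, 10.0]), cfg, rng)
        assert path.shape[0] > 50  # Rayleigh(mean 500) rarely below 50 μm

    def test_periodic_wrap(self):
        cfg = TopologyConfig(N=10, axon_angle_sd=0.0)

        class EastRng:
            def __init__(self):
                self._r = np.random.default_rng(0)
            def rayleigh(self, s):
                return 300.0
            def uniform(self, a, b):
                return 0.0  # due east
            def normal(self, m, s, n):
                return np.zeros(n)
        path = grow_axon(np.array([1400.0, 700.0]), cfg, EastRng())
        assert np.all((path[:, 0] >= 0) & (path[:, 0] < 1500))
        assert path[:, 0].min() < 100  # wrapped past x = L

    def test_consecutive_cells_are_8_adjacent(self):
        cfg = TopologyConfig(N=10)
        rng = np.random.default_rng(21)
        path = grow_axon(np.array([750.0, 750.0]), cfg, rng)
        d = np.abs(np.diff(path, axis=0))
        d = np.minimum(d, 1500 - d)  # wrap seam
        assert np.all(d.max(axis=1) == 1)


class TestEstablishSynapses:
    def test_zero_alpha_empty(self):
        cfg = TopologyConfig(N=3, L=300.0)
        soma = np.array([[50.0, 50.0], [150.0, 150.0], [250.0, 50.0]])
        radii = np.full(3, 120.0)
        path = np.column_stack([np.arange(100, 200), np.full(100, 150)])
        out = establish_synapses(0, path, soma, radii,
                                 GenotypeParams("null", 0.0, 1.0),
                                 WT_CONSTANTS, cfg, seed=4)
        assert out == []

    def test_autapse_ban(self):
        cfg = TopologyConfig(N=1, L=300.0)
        soma = np.array([[150.0, 150.0]])
        radii = np.array([140.0])
        path = np.column_stack([np.arange(60, 240), np.full(180, 160)])
        out = establish_synapses(0, path, soma, radii, GENOTYPES["WT"],
                                 WT_CONSTANTS, cfg, seed=4)
        assert out == []

    def test_binomial_law_at_constant_radius(self):
        # 100 cells on a ring at r≈80 μm around a single covering target
        cfg = TopologyConfig(N=2, L=1000.0)
        center = np.array([500.0, 500.0])
        theta = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        pts = center + 80.0 * np.column_stack([np.cos(theta), np.sin(theta)])
        cells = np.unique(np.floor(pts).astype(np.int64), axis=0)
        soma = np.array([[100.0, 100.0], center])
        radii = np.array([50.0, 200.0])
        table = scp_table(GENOTYPES["WT"], WT_CONSTANTS)
        dists = np.hypot(*(cells + 0.5 - center).T)
        p_exact = np.array([scp_lookup(d, table, 0.25) for d in dists])
        mean_expected = p_exact.sum()
        var = (p_exact * (1 - p_exact)).sum()
        counts = []
        for s in range(300):
            out = dict(establish_synapses(0, cells, soma, radii,
                                          GENOTYPES["WT"], WT_CONSTANTS, cfg,
                                          seed=1000 + s))
            counts.append(out.get(1, 0))
        se = np.sqrt(var / len(counts))
        assert abs(np.mean(counts) - mean_expected) < 3 * se

    def test_soma_core_excluded(self):
        # cells inside the target's soma never form contacts
        cfg = TopologyConfig(N=2, L=300.0)
        soma = np.array([[150.0, 150.0], [20.0, 20.0]])
        radii = np.array([100.0, 50.0])
        inside = np.column_stack([np.arange(146, 154), np.full(8, 150)])
        out = establish_synapses(1, inside, soma, radii, GENOTYPES["WT"],
                                 WT_CONSTANTS, cfg, seed=9)
        assert out == []


class TestGenerateNetwork:
    def test_smoke_contract(self):
        cfg = TopologyConfig(N=10, L=300.0)
        net = generate_network(cfg, GENOTYPES["WT"], seed=1)
        assert net.weights.diagonal().sum() == 0
        if net.weights.nnz:
            assert net.weights.data.min() >= 1
        assert len(net.geometry) == 10

    def test_determinism(self):
        cfg = TopologyConfig(N=40, L=300.0)
        a = generate_network(cfg, GENOTYPES["WT"], seed=7)
        b = generate_network(cfg, GENOTYPES["WT"], seed=7)
        assert (a.weights != b.weights).nnz == 0
        for ga, gb in zip(a.geometry, b.geometry):
            np.testing.assert_array_equal(ga.axon_path, gb.axon_path)

    def test_bruteforce_oracle_equivalence(self):
        # all-pairs, all-cells reference consumes the identical RNG stream
        cfg = TopologyConfig(N=18, L=300.0)
        for g in ("WT", "Ts65Dn"):
            fast = generate_network(cfg, GENOTYPES[g], seed=3)
            slow = generate_network(cfg, GENOTYPES[g], seed=3,
                                    _bruteforce=True)
            assert (fast.weights != slow.weights).nnz == 0

    def test_alpha_monotonicity(self):
        cfg = TopologyConfig(N=150, L=500.0)
        lo = [generate_network(cfg, GenotypeParams("lo", 0.5, 1.0),
                               seed=s).weights.nnz for s in range(5)]
        hi = [generate_network(cfg, GenotypeParams("hi", 1.0, 1.0),
                               seed=s).weights.nnz for s in range(5)]
        assert np.mean(hi) > np.mean(lo)

    def test_genotype_density_ordering_small(self):
        dens = {}
        for name, g in GENOTYPES.items():
            cfg = TopologyConfig(N=200, L=600.0, dend_mean=g.R_bar)
            dens[name] = np.mean([
                network_density(generate_network(cfg, g, seed=s))
                for s in range(4)])
        assert dens["WT"] > dens["Ts65Dn"] > dens["TgDyrk1A"]


class TestNetworkIO:
    def test_mtx_roundtrip(self, small_wt_net, tmp_path):
        net, cfg = small_wt_net
        save_network(net, tmp_path / "net", cfg)
        back = load_network(tmp_path / "net")
        assert (back.weights != net.weights).nnz == 0
        assert back.genotype == net.genotype
        assert back.seed == net.seed

    def test_mtx_is_one_based_integer(self, small_wt_net, tmp_path):
        net, cfg = small_wt_net
        save_network(net, tmp_path / "net")
        header = (tmp_path / "net.mtx").read_text().splitlines()[0]
        assert "integer" in header

    def test_geometry_tsv(self, small_wt_net, tmp_path):
        net, _ = small_wt_net
        save_geometry(net, tmp_path / "geo.tsv")
        lines = (tmp_path / "geo.tsv").read_text().splitlines()
        assert lines[0].split("\t") == ["neuron_id", "x_um", "y_um",
                                        "dend_radius_um"]
        assert len(lines) == net.N + 1
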