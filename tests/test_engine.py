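import numpy as np
import pytest
from click.testing import CliRunner

from phasekit import engine, evalsim, io_formats, pbwt
from phasekit.cli import main as cli_main

from conftest import mean_ser


class TestSchedule:
    def test_default_schedule(self):
        it = engine.parse_schedule(engine.DEFAULT_SCHEDULE)
        assert len(it) == 15
        assert it.count("p") == 3
        assert it == list("bbbbb" "p" "b" "p" "b" "p" "mmmmm")

    def test_bad_token_errors(self):
        with pytest.raises(ValueError):
            engine.parse_schedule("3b,2x")

    def test_config_validates_window(self):
        with pytest.raises(ValueError):
            engine.RunConfig(window_bp=100, overlap_bp=200)


class TestWindows:
    def _vt(self, pos):
        pos = np.asarray(pos)
        return io_formats.VariantTable(
            chrom="1", pos=pos, ids=["."] * len(pos), ref=["A"] * len(pos),
            alt=["C"] * len(pos), cm=pos * 1e-6)

    def test_short_chromosome_single_window(self):
        vt = self._vt(np.arange(1, 1_000_000, 10_000))
        wins = engine.make_windows(vt, 2_000_000, 250_000)
        assert len(wins) == 1
        assert wins[0].lo_idx == 0 and wins[0].hi_idx == vt.n_sites

    def test_every_variant_covered(self):
        vt = self._vt(np.arange(1, 5_000_000, 3_333))
        wins = engine.make_windows(vt, 2_000_000, 250_000)
        covered = np.zeros(vt.n_sites, bool)
        for w in wins:
            covered[w.lo_idx:w.hi_idx] = True
        assert covered.all()

    def test_starts_advance_by_step(self):
        vt = self._vt(np.arange(1, 6_000_000, 1_000))
        wins = engine.make_windows(vt, 2_000_000, 250_000)
        starts = [w.start_bp for w in wins]
        assert all(b - a == 1_750_000 for a, b in zip(starts, starts[1:]))


class TestLigate:
    def _mk(self, g_row, cut, flip_second):
        L = len(g_row)
        rng = np.random.default_rng(0)
        h1 = rng.integers(0, 2, L).astype(np.uint8)
        h2 = np.where(g_row == 1, 1 - h1, h1).astype(np.uint8)
        windows = [engine.Window(0, 0, 0, cut + 20),
                   engine.Window(0, 0, cut, L)]
        p1 = (h1[:cut + 20].copy(), h2[:cut + 20].copy())
        if flip_second:
            p2 = (h2[cut:].copy(), h1[cut:].copy())
        else:
            p2 = (h1[cut:].copy(), h2[cut:].copy())
        return (h1, h2), windows, [p1, p2]

    def test_flip_applied(self):
        g = np.ones(100, np.int8)
        truth, windows, pairs = self._mk(g, cut=50, flip_second=True)
        h1, h2 = engine.ligate_windows(pairs, windows, g)
        assert evalsim.switch_error_rate((h1, h2), truth) == 0.0

    def test_identical_overlap_unchanged(self):
        g = np.ones(100, np.int8)
        truth, windows, pairs = self._mk(g, cut=50, flip_second=False)
        h1, h2 = engine.ligate_windows(pairs, windows, g)
        np.testing.assert_array_equal(h1, truth[0])

    def test_three_windows_planted_orientations(self):
        g = np.ones(150, np.int8)
        rng = np.random.default_rng(1)
        h1 = rng.integers(0, 2, 150).astype(np.uint8)
        h2 = (1 - h1).astype(np.uint8)
        windows = [engine.Window(0, 0, 0, 60), engine.Window(0, 0, 40, 110),
                   engine.Window(0, 0, 90, 150)]
        flips = [False, True, True]
        pairs = []
        for w, f in zip(windows, flips):
            a, b = h1[w.lo_idx:w.hi_idx], h2[w.lo_idx:w.hi_idx]
            pairs.append((b.copy(), a.copy()) if f else (a.copy(), b.copy()))
        got = engine.ligate_windows(pairs, windows, g)
        assert evalsim.switch_error_rate(got, (h1, h2)) == 0.0


@pytest.fixture(scope="module")
def phased_small():
    truth = evalsim.simulate_population(12, 40, 400, span_bp=500_000,
                                        recomb_per_bp=1e-6, maf_min=0.1,
                                        seed=21)
    gm = truth.genotype_matrix()
    vt = truth.variant_table()
    cfg = engine.RunConfig(seed=5)
    res = engine.phase(gm, vt, cfg)
    return truth, gm, vt, cfg, res


class TestPhase:
    def test_genotype_consistency(self, phased_small):
        truth, gm, vt, cfg, res = phased_small
        h = res.haplotypes
        np.testing.assert_array_equal(
            h[0::2].astype(np.int16) + h[1::2], gm.codes)

    def test_improves_on_initialization(self, phased_small):
        truth, gm, vt, cfg, res = phased_small
        H0 = pbwt.pbwt_init_phase(gm, vt, cfg.seed)
        assert mean_ser(res.haplotypes, truth) < mean_ser(H0, truth)

    def test_deterministic(self, phased_small, tmp_path):
        truth, gm, vt, cfg, res = phased_small
        res2 = engine.phase(gm, vt, engine.RunConfig(seed=5))
        np.testing.assert_array_equal(res.haplotypes, res2.haplotypes)
        np.testing.assert_array_equal(res.certainty, res2.certainty)
        a, b = tmp_path / "a.vcf", tmp_path / "b.vcf"
        io_formats.write_phased_vcf(str(a), vt, res.haplotypes,
                                    gm.sample_ids, res.certainty)
        io_formats.write_phased_vcf(str(b), vt, res2.haplotypes,
                                    gm.sample_ids, res2.certainty)
        assert a.read_bytes() == b.read_bytes()

    def test_certainty_in_unit_interval(self, phased_small):
        _, _, _, _, res = phased_small
        assert (res.certainty >= 0).all() and (res.certainty <= 1 + 1e-12).all()

    def test_perfect_scaffold_forces_truth(self):
        truth = evalsim.simulate_population(10, 25, 250, span_bp=300_000,
                                            maf_min=0.1, seed=31)
        sc = evalsim.simulate_scaffold(truth, coverage_fraction=1.0, seed=1)
        gm = truth.genotype_matrix()
        res = engine.phase(gm, truth.variant_table(),
                           engine.RunConfig(seed=2), scaffold=sc)
        assert mean_ser(res.haplotypes, truth) == 0.0
        for (i, l), allele in sc.items():
            assert res.haplotypes[2 * i, l] == allele

    def test_multi_window_run(self):
        truth = evalsim.simulate_population(
            12, 30, 900, span_bp=4_000_000, recomb_per_bp=5e-7,
            maf_min=0.1, seed=41)
        gm = truth.genotype_matrix()
        vt = truth.variant_table()
        res = engine.phase(gm, vt, engine.RunConfig(seed=3))
        assert res.diagnostics["n_windows"] >= 2
        h = res.haplotypes
        np.testing.assert_array_equal(
            h[0::2].astype(np.int16) + h[1::2], gm.codes)
        assert mean_ser(h, truth) < 0.15

    def test_reference_panel_helps_small_panel(self):
        big = evalsim.simulate_population(15, 120, 400, span_bp=500_000,
                                          maf_min=0.1, seed=51)
        n_main = 8
        gm_all = big.genotype_matrix()
        gm = io_formats.GenotypeMatrix(
            codes=gm_all.codes[:n_main].copy(),
            sample_ids=gm_all.sample_ids[:n_main])
        vt = big.variant_table()
        ref = big.haplotypes[2 * n_main:]
        res_ref = engine.phase(gm, vt, engine.RunConfig(seed=4),
                               reference=ref)
        res_null = engine.phase(gm, vt, engine.RunConfig(seed=4))

        def ser(h):
            out = []
            for i in range(n_main):
                t1, t2 = big.pair(i)
                if int((t1 != t2).sum()) < 2:
                    continue
                out.append(evalsim.switch_error_rate(
                    (h[2 * i], h[2 * i + 1]), (t1, t2)))
            return float(np.mean(out))
        h = res_ref.haplotypes
        np.testing.assert_array_equal(
            h[0::2].astype(np.int16) + h[1::2], gm.codes)
        assert ser(res_ref.haplotypes) <= ser(res_null.haplotypes)


def test_reference_haplotypes_enter_conditioning_set():
    truth = evalsim.simulate_population(10, 30, 300, span_bp=400_000,
                                        maf_min=0.1, seed=101)
    n_main = 5
    gm = io_formats.GenotypeMatrix(
        codes=truth.genotypes()[:n_main].copy(),
        sample_ids=[f"s{i}" for i in range(n_main)])
    vt = truth.variant_table()
    ref = truth.haplotypes[2 * n_main:]
    cfg = engine.RunConfig(seed=11)
    H = pbwt.pbwt_init_phase(gm, vt, cfg.seed)
    H_all = np.vstack([H, ref])
    windows = engine.make_windows(vt, cfg.window_bp, cfg.overlap_bp)
    state = pbwt.pbwt_build(H_all, cfg.stride,
                            [w.hi_idx - 1 for w in windows])
    hit_ref = False
    for i in range(n_main):
        got = pbwt.select_conditioning_set(
            state, (2 * i, 2 * i + 1), windows[0].lo_idx, windows[0].hi_idx,
            cfg.p_neighbors, H=H_all)
        if (np.asarray(got) >= 2 * n_main).any():
            hit_ref = True
    assert hit_ref


class TestIbd2Exclusion:
    def test_duplicated_individual_never_conditioned_on(self):
        truth = evalsim.simulate_population(10, 20, 300, span_bp=400_000,
                                            maf_min=0.1, seed=61)
        codes = truth.genotypes()
        codes[1] = codes[0]   # individual 1 duplicates individual 0
        gm = io_formats.GenotypeMatrix(
            codes=codes, sample_ids=[f"s{i}" for i in range(20)])
        vt = truth.variant_table()
        cfg = engine.RunConfig(seed=6)
        windows = engine.make_windows(vt, cfg.window_bp, cfg.overlap_bp)
        span = int(vt.pos[-1] - vt.pos[0] + 1)
        cons = pbwt.pbwt_long_genotype_matches(
            gm, vt, windows, min_span_bp=min(cfg.window_bp, span))
        assert any({c.i, c.j} == {0, 1} for c in cons)
        # run and spy on conditioning sets via update_individual's exclusions
        res = engine.phase(gm, vt, cfg)
        h = res.haplotypes
        np.testing.assert_array_equal(
            h[0::2].astype(np.int16) + h[1::2], codes)

    def test_exclusion_contract_in_update(self):
        truth = evalsim.simulate_population(8, 10, 200, span_bp=300_000,
                                            maf_min=0.1, seed=71)
        codes = truth.genotypes()
        codes[1] = codes[0]
        gm = io_formats.GenotypeMatrix(
            codes=codes, sample_ids=[f"s{i}" for i in range(10)])
        vt = truth.variant_table()
        cfg = engine.RunConfig(seed=8)
        windows = engine.make_windows(vt, cfg.window_bp, cfg.overlap_bp)
        H = pbwt.pbwt_init_phase(gm, vt, cfg.seed)
        state = pbwt.pbwt_build(H, cfg.stride,
                                [w.hi_idx - 1 for w in windows])
        win = windows[0]
        got = pbwt.select_conditioning_set(
            state, (0, 1), win.lo_idx, win.hi_idx, cfg.p_neighbors,
            exclude={2, 3}, H=H)
        assert not {0, 1, 2, 3} & set(int(x) for x in got)


class TestCli:
    def test_missing_input_usage_error(self):
        runner = CliRunner()
        result = runner.invoke(cli_main, ["--output", "x.vcf"])
        assert result.exit_code != 0

    def test_schedule_flag_parses(self):
        assert len(engine.parse_schedule("5b,1p,1b,1p,1b,1p,5m")) == 15

    def test_end_to_end_smoke(self, tmp_path):
        truth = evalsim.simulate_population(15, 50, 300, span_bp=400_000,
                                            maf_min=0.1, seed=81)
        vcf_in = tmp_path / "in.vcf"
        evalsim.write_truth_vcf(str(vcf_in), truth)
        map_path = tmp_path / "map.txt"
        evalsim.write_genetic_map(str(map_path), 400_000)
        out = tmp_path / "out.vcf"
        runner = CliRunner()
        result = runner.invoke(cli_main, [
            "--input", str(vcf_in), "--output", str(out),
            "--map", str(map_path), "--seed", "3",
            "--log", str(tmp_path / "run.log")])
        assert result.exit_code == 0, result.output
        vt2, haps = io_formats.read_haplotypes(str(out))
        np.testing.assert_array_equal(
            haps[0::2].astype(np.int16) + haps[1::2], truth.genotypes())
        assert (tmp_path / "run.log").read_text() != ""

    def test_cli_with_scaffold_and_ps(self, tmp_path):
        truth = evalsim.simulate_population(10, 20, 200, span_bp=300_000,
                                            maf_min=0.1, seed=91)
        ps = evalsim.simulate_phase_sets(truth, coverage_fraction=0.8, seed=2)
        sc = evalsim.simulate_scaffold(truth, coverage_fraction=0.3, seed=3)
        vcf_in = tmp_path / "in.vcf"
        evalsim.write_truth_vcf(str(vcf_in), truth, phase_sets=ps)
        sc_path = tmp_path / "sc.vcf"
        evalsim.write_scaffold_vcf(str(sc_path), truth, sc)
        out = tmp_path / "out.vcf"
        runner = CliRunner()
        result = runner.invoke(cli_main, [
            "--input", str(vcf_in), "--output", str(out),
            "--scaffold", str(sc_path), "--use-ps", "0.0001", "--seed", "3"])
        assert result.exit_code == 0, result.output
        _, haps = io_formats.read_haplotypes(str(out))
        for (i, l), allele in sc.items():
            assert haps[2 * i, l] == allele
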