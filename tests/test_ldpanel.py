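import numpy as np
import pytest

from trioscan.errors import EmptyPanelError, MonomorphicVariantError, PanelLookupError, PhasingError
from trioscan.ldpanel import LDConfig, compute_r2, find_proxies, load_panel
from trioscan.sumstats import TraitType

from conftest import make_panel, make_record, r2_oracle


def _random_columns(rng, n_variants, n_haps):
    """Polymorphic 0/1 columns, some correlated, some independent."""
    cols = []
    for i in range(n_variants):
        while True:
            if cols and rng.random() < 0.5:
                base = cols[rng.integers(len(cols))]
                col = np.where(rng.random(n_haps) < 0.2, 1 - base, base)
            else:
                col = (rng.random(n_haps) < rng.uniform(0.2, 0.8)).astype(int)
            if 0 < col.mean() < 1:
                break
        cols.append(col.astype(np.int8))
    return cols


class TestLoadPanel:
    def test_dimensions(self, vcf_file):
        gts = lambda bits: [f"{bits[2*i]}|{bits[2*i+1]}" for i in range(4)]
        records = [
            ("1", 100 * (i + 1), f"rs{i}", "A", "G", gts([i % 2, 1, 0, 1, 0, 0, 1, 0]))
            for i in range(10)
        ]
        panel = load_panel(vcf_file(records, n_samples=4))
        assert panel.n_rows == 8 and panel.n_variants == 10
        assert panel.mode == "phased"

    def test_indel_skipped(self, vcf_file):
        g = ["0|1", "1|0"]
        records = [("1", 100 * (i + 1), f"rs{i}", "A", "G", g) for i in range(9)]
        records.insert(4, ("1", 10_000, "rsindel", "A", "AT", g))
        panel = load_panel(vcf_file(records, n_samples=2))
        assert panel.n_variants == 9
        assert "rsindel" not in panel

    def test_multiallelic_skipped(self, vcf_file):
        records = [
            ("1", 100, "rs0", "A", "G", ["0|1", "1|0"]),
            ("1", 200, "rsmulti", "A", "G,T", ["0|1", "1|2"]),
        ]
        assert load_panel(vcf_file(records, n_samples=2)).n_variants == 1

    def test_unphased_strict_raises(self, vcf_file):
        records = [("1", 100, "rs0", "A", "G", ["0/1", "1|0"])]
        with pytest.raises(PhasingError, match="rs0"):
            load_panel(vcf_file(records, n_samples=2))

    def test_unphased_dosage_fallback(self, vcf_file):
        records = [
            ("1", 100, "rs0", "A", "G", ["0/1", "1/1", "0/0"]),
            ("1", 200, "rs1", "A", "G", ["0/1", "1/1", "0/0"]),
        ]
        panel = load_panel(vcf_file(records, n_samples=3), allow_unphased=True)
        assert panel.mode == "dosage"
        assert panel.n_rows == 3  # one row per sample in dosage mode
        assert compute_r2(panel, "rs0", "rs1") == pytest.approx(1.0)

    def test_empty_panel_error(self, vcf_file):
        records = [("1", 100, "rsindel", "A", "AT", ["0|1", "1|0"])]
        with pytest.raises(EmptyPanelError):
            load_panel(vcf_file(records, n_samples=2))


class TestComputeR2:
    def test_identical_columns(self):
        panel = make_panel([[0, 0, 1, 1], [0, 0, 1, 1]])
        assert compute_r2(panel, "rs1", "rs2") == pytest.approx(1.0)

    def test_independent_columns_zero(self):
        # p_AB = p_A * p_B exactly: (0,0,1,1) vs (0,1,0,1)
        panel = make_panel([[0, 0, 1, 1], [0, 1, 0, 1]])
        assert compute_r2(panel, "rs1", "rs2") == pytest.approx(0.0, abs=1e-15)

    def test_matches_oracle_random_8_haplotypes(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            cols = _random_columns(rng, 2, 8)
            panel = make_panel(cols)
            assert compute_r2(panel, "rs1", "rs2") == pytest.approx(
                r2_oracle(cols[0], cols[1]), abs=1e-12
            )

    def test_symmetry_exhaustive_small_panels(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            cols = _random_columns(rng, 5, 12)
            panel = make_panel(cols)
            for i in range(5):
                for j in range(i + 1, 5):
                    a, b = f"rs{i + 1}", f"rs{j + 1}"
                    assert compute_r2(panel, a, b) == pytest.approx(compute_r2(panel, b, a), abs=0)

    def test_invariant_under_allele_swap(self):
        rng = np.random.default_rng(3)
        cols = _random_columns(rng, 2, 20)
        base = compute_r2(make_panel(cols), "rs1", "rs2")
        flipped = compute_r2(make_panel([1 - cols[0], cols[1]]), "rs1", "rs2")
        assert flipped == pytest.approx(base, abs=1e-12)

    def test_monomorphic_raises(self):
        panel = make_panel([[0, 0, 0, 0], [0, 1, 0, 1]])
        with pytest.raises(MonomorphicVariantError):
            compute_r2(panel, "rs1", "rs2")

    def test_cross_chromosome_rejected(self):
        panel = make_panel([[0, 1, 0, 1], [0, 1, 1, 0]], chrom=["1", "2"])
        with pytest.raises(ValueError):
            compute_r2(panel, "rs1", "rs2")

    def test_missing_variant(self):
        panel = make_panel([[0, 1, 0, 1]])
        with pytest.raises(PanelLookupError):
            compute_r2(panel, "rs1", "rs99")


class TestFindProxies:
    def _setup(self):
        col = [0, 1] * 10
        proxy = list(col)
        proxy[0] = 1  # one flip over 20 haplotypes: r² ≈ 0.82, above the 0.8 floor
        indep = ([1, 1, 0, 0] * 5)
        panel = make_panel(
            [col, proxy, indep],
            chrom=["1", "1", "2"],
            positions=[1_000_000, 1_050_000, 1_000_000],
            rsids=["rsA", "rsB", "rsC"],
        )
        anchor = make_record(rsid="rsA", chrom="1", pos=1_000_000)
        return panel, anchor

    def test_planted_proxy_found_distractor_ignored(self):
        panel, anchor = self._setup()
        cands = [
            make_record(rsid="rsB", chrom="1", pos=1_050_000, trait_type=TraitType.METABOLITE, trait="m1"),
            make_record(rsid="rsC", chrom="2", pos=1_000_000, trait_type=TraitType.METABOLITE, trait="m2"),
        ]
        pairs = find_proxies(panel, anchor, cands, LDConfig())
        assert [p.rsid_b for p in pairs] == ["rsB"]
        assert pairs[0].r2 == pytest.approx(r2_oracle(panel.column("rsA"), panel.column("rsB")), abs=1e-12)
        assert pairs[0].r2 > 0.8

    def test_window_boundary(self):
        col = [0, 0, 1, 1]
        panel = make_panel(
            [col, col, col],
            positions=[1_000_000, 1_250_000, 1_250_001],
            rsids=["rsA", "rsIn", "rsOut"],
        )
        anchor = make_record(rsid="rsA", pos=1_000_000)
        cands = [
            make_record(rsid="rsIn", pos=1_250_000, trait_type=TraitType.METABOLITE, trait="m"),
            make_record(rsid="rsOut", pos=1_250_001, trait_type=TraitType.METABOLITE, trait="m"),
        ]
        pairs = find_proxies(panel, anchor, cands, LDConfig(window_bp=250_000))
        assert [p.rsid_b for p in pairs] == ["rsIn"]  # 250,000 in; 250,001 out

    def test_r2_exactly_at_floor_excluded(self):
        col = [0, 1, 0, 1]
        panel = make_panel([col, col], rsids=["rsA", "rsB"], positions=[1000, 2000])
        anchor = make_record(rsid="rsA", pos=1000)
        cand = [make_record(rsid="rsB", pos=2000, trait_type=TraitType.METABOLITE, trait="m")]
        assert find_proxies(panel, anchor, cand, LDConfig(r2_min=1.0)) == []
        assert len(find_proxies(panel, anchor, cand, LDConfig(r2_min=0.999))) == 1

    def test_anchor_missing_raises(self):
        panel = make_panel([[0, 1, 0, 1]])
        with pytest.raises(PanelLookupError):
            find_proxies(panel, make_record(rsid="rsZ"), [], LDConfig())

    def test_candidate_missing_skipped(self):
        col = [0, 1, 0, 1]
        panel = make_panel([col], rsids=["rsA"], positions=[1000])
        anchor = make_record(rsid="rsA", pos=1000)
        cand = [make_record(rsid="rsGone", pos=1500, trait_type=TraitType.METABOLITE, trait="m")]
        assert find_proxies(panel, anchor, cand, LDConfig()) == []

    def test_monotonicity_in_window_and_floor(self):
        rng = np.random.default_rng(11)
        cols = _random_columns(rng, 10, 30)
        positions = sorted(rng.integers(1, 600_000, size=10).tolist())
        panel = make_panel(cols, positions=positions)
        anchor = make_record(rsid="rs1", pos=positions[0])
        cands = [
            make_record(rsid=f"rs{i + 1}", pos=positions[i], trait_type=TraitType.METABOLITE, trait=f"m{i}")
            for i in range(1, 10)
        ]
        base = {p.rsid_b for p in find_proxies(panel, anchor, cands, LDConfig(window_bp=200_000, r2_min=0.5))}
        wider = {p.rsid_b for p in find_proxies(panel, anchor, cands, LDConfig(window_bp=400_000, r2_min=0.5))}
        looser = {p.rsid_b for p in find_proxies(panel, anchor, cands, LDConfig(window_bp=200_000, r2_min=0.2))}
        assert base <= wider and base <= looser

    def test_sort_order(self):
        rng = np.random.default_rng(5)
        cols = _random_columns(rng, 8, 40)
        positions = [1000 * (i + 1) for i in range(8)]
        panel = make_panel(cols, positions=positions)
        anchor = make_record(rsid="rs1", pos=1000)
        cands = [
            make_record(rsid=f"rs{i + 1}", pos=positions[i], trait_type=TraitType.METABOLITE, trait="m")
            for i in range(1, 8)
        ]
        pairs = find_proxies(panel, anchor, cands, LDConfig(r2_min=0.0))
        keys = [(-p.r2, p.distance_bp, p.rsid_b) for p in pairs]
        assert keys == sorted(keys)


def test_oracle_equivalence_all_pairs_small_panels():
    """compute_r2 agrees with the haplotype-count oracle on every pair."""
    rng = np.random.default_rng(123)
    for _ in range(20):
        n_var = int(rng.integers(2, 12))
        cols = _random_columns(rng, n_var, int(rng.integers(6, 30)))
        panel = make_panel(cols)
        for i in range(n_var):
            for j in range(i + 1, n_var):
                got = compute_r2(panel, f"rs{i + 1}", f"rs{j + 1}")
                assert got == pytest.approx(r2_oracle(cols[i], cols[j]), abs=1e-12)
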