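import filecmp
import math

import numpy as np
import pytest

from tpmtyper import (
    SimParams,
    Stratum,
    ct_from_copies,
    estimate_lod,
    paper_panel_strata,
    process_plate,
    simulate_panel,
    simulate_well,
)
from tpmtyper.simulate import copies_per_reaction


class TestCtFromCopies:
    def test_intercept_is_single_copy_ct(self):
        assert ct_from_copies(1.0, True, SimParams()) == 38.0

    def test_doubling_efficiency_log2(self):
        # 1024 copies = 2^10 -> 10 cycles earlier than one copy
        assert ct_from_copies(1024.0, True, SimParams()) == pytest.approx(28.0)

    def test_mismatch_penalty_additive(self):
        params = SimParams()
        assert ct_from_copies(1024.0, False, params) == pytest.approx(40.0)
        # 8 mismatched copies never cross within 45 cycles
        assert ct_from_copies(8.0, False, params) == pytest.approx(47.0)

    def test_fourfold_is_delta_ct_two(self):
        """The delta-Ct = 2 threshold equals a 4-fold template difference."""
        params = SimParams()
        for copies in (10.0, 1e3, 1e6):
            delta = ct_from_copies(copies, True, params) - ct_from_copies(
                4 * copies, True, params
            )
            assert delta == pytest.approx(2.0, abs=1e-12)

    def test_nonpositive_copies_error(self):
        with pytest.raises(ValueError):
            ct_from_copies(0.0, True, SimParams())


def test_ng_to_copies_conversion():
    # 1 ng/uL = 1000 copies/uL; 5 uL template per reaction
    assert copies_per_reaction(1.0, SimParams()) == 5000.0
    assert copies_per_reaction(10.0, SimParams()) == 50000.0


def test_simulate_well_routes(rng):
    params = SimParams()
    matched = simulate_well("hom_wt", "wt", 1e5, params, rng)
    assert matched.target_ct is not None
    expected = ct_from_copies(1e5, True, params)
    assert matched.target_ct == pytest.approx(expected, abs=1.0)
    mismatched = simulate_well("hom_wt", "var", 1e5, params, rng)
    assert mismatched.target_ct is not None
    assert mismatched.target_ct >= matched.target_ct + params.mismatch_penalty - 3 * 1.0


def test_simulate_well_zero_template(rng):
    sim = simulate_well("hom_wt", "wt", 0.0, SimParams(), rng)
    assert sim.target_ct is None
    assert sim.ipc_ct is not None


def test_delta_ct_equals_log_ratio_without_noise(noise_free_params, rng):
    params = noise_free_params
    for c1, c2 in ((1e5, 1e3), (4e4, 1e4)):
        w1 = simulate_well("hom_wt", "wt", c1, params, rng)
        w2 = simulate_well("hom_wt", "wt", c2, params, rng)
        expected = math.log(c1 / c2, params.efficiency)
        # Poisson sampling at p=1 leaves only counting jitter (~log2(1+1/sqrt(c)))
        assert w2.target_ct - w1.target_ct == pytest.approx(expected, abs=0.2)


def test_paper_panel_counts(panel):
    plate = simulate_panel(paper_panel_strata(), panel, SimParams(), curves=False)
    assert len(plate.metas) == 246
    assert len(plate.wells) == 1476
    groups = plate.truth_samples.groupby("group")["sample_id"].nunique()
    assert groups["patient"] == 244
    assert groups["control"] == 2
    assert set(plate.truth_samples.query("group == 'control'")["sample_id"]) == {
        "NA09301",
        "NA03579",
    }
    counts = plate.truth_samples["diplotype"].value_counts()
    assert counts["*1/*1"] == 234 and counts["*1/*3C"] == 11 and counts["*1/*3B"] == 1


def test_single_wildtype_sample_var_wells_late_or_silent(panel, rng):
    plate = simulate_panel([Stratum("*1/*1", 1, 10.0)], panel, SimParams(), curves=False)
    assert len(plate.wells) == 6
    for w in plate.wells:
        ct = plate.true_cts[(w.well_id, "TARGET")]
        if w.primer_allele == "var":
            wt_well = next(
                ww for ww in plate.wells
                if ww.snp_id == w.snp_id and ww.primer_allele == "wt"
            )
            wt_ct = plate.true_cts[(wt_well.well_id, "TARGET")]
            assert ct is None or ct >= wt_ct + 8.0


def test_stratum_validation():
    with pytest.raises(ValueError, match="n must be >= 1"):
        Stratum("*1/*1", 0, 10.0)


def test_seed_determinism(tmp_path, panel):
    strata = [Stratum("*1/*3C", 2, 10.0)]
    for d in ("a", "b"):
        (tmp_path / d).mkdir()
        simulate_panel(strata, panel, SimParams(seed=99)).write(str(tmp_path / d))
    for name in ("layout.csv", "curves.csv", "samples.csv", "truth.tsv"):
        assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False)
    simulate_panel(strata, panel, SimParams(seed=100)).write(str(tmp_path / "a"))
    assert not filecmp.cmp(tmp_path / "a" / "curves.csv", tmp_path / "b" / "curves.csv",
                           shallow=False)


def test_full_pipeline_recovers_all_diplotypes_noise_free(panel, noise_free_params):
    """With no noise and perfect detection, simulate -> Ct estimate -> call
    -> diplotype recovers the truth for every one of the 15 allele pairs
    (phase-ambiguous pairs scored against the candidate set)."""
    from itertools import combinations_with_replacement

    names = [a.name for a in panel.alleles]
    strata = [
        Stratum("/".join(sorted(pair)), 1, 10.0)
        for pair in combinations_with_replacement(names, 2)
    ]
    assert len(strata) == 15
    plate = simulate_panel(strata, panel, noise_free_params)
    results = process_plate(plate.wells, plate.metas, panel)
    truth = plate.truth_samples.set_index("sample_id")["diplotype"]
    for res in results:
        expected = truth[res.sample_id]
        dip = res.diplotype_call
        candidates = [dip.allele_pair] + [pair for pair, _ in dip.alternatives]
        assert tuple(expected.split("/")) in candidates, res.sample_id
        if not dip.ambiguous:
            assert dip.diplotype == expected


class TestLod:
    def test_default_assay_lod_is_100_copies(self):
        result = estimate_lod(params=SimParams(seed=17))
        assert result.lod_copies_per_reaction == 100.0

    def test_719_preset_lod_is_1000_copies(self):
        result = estimate_lod(snp_id="c.719A>G", params=SimParams(seed=17))
        assert result.lod_copies_per_reaction == 1000.0

    def test_ideal_assay_detects_100_copies(self):
        params = SimParams(detection_eff=1.0, detection_eff_by_snp={}, seed=17)
        result = estimate_lod(params=params)
        assert result.lod_copies_per_reaction <= 100.0

    def test_replicate_minimum(self):
        with pytest.raises(ValueError, match="replicates"):
            estimate_lod(replicates=3)

    def test_grid_must_decrease(self):
        with pytest.raises(ValueError, match="decreasing"):
            estimate_lod(grid=(1e2, 1e3))


def test_efficiency_bounds():
    with pytest.raises(ValueError):
        SimParams(efficiency=2.5)
    with pytest.raises(ValueError):
        SimParams(detection_eff=0.0)
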