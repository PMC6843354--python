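"""Ground-truth generator: geometry, determinism, noise model, HDX kinetics."""

import dataclasses
import json

import numpy as np
import pytest

from msbridge.chem_masses import CrosslinkerDef, doublet_delta, DSG, DSS
from msbridge.synthetic_data import (
    DEFAULT_FORWARD,
    DEFAULT_REVERSE,
    ScenarioConfig,
    build_scenario,
    gen_duplex_coords,
    gen_fold,
    gen_hdx,
    gen_peaklists,
    plant_crosslinks,
    protection_factors,
    random_protein,
    residue_uptake_truth,
    write_scenario,
)


class TestFoldGeometry:
    def test_bond_lengths_exact(self):
        cfg = ScenarioConfig(seed=1, protein_length=60)
        coords = gen_fold(cfg)
        steps = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        assert steps.min() >= 3.79 and steps.max() <= 3.81

    def test_self_avoidance(self):
        cfg = ScenarioConfig(seed=1, protein_length=60)
        coords = gen_fold(cfg)
        n = len(coords)
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        mask = np.abs(np.subtract.outer(range(n), range(n))) > 1
        assert d[mask].min() >= cfg.excluded_radius - 1e-9

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            gen_fold(ScenarioConfig(protein_length=2))

    def test_duplex_rise_and_pitch(self):
        coords = gen_duplex_coords(13)
        # 12 steps of 3.4 A rise: 40.8 A end-to-end along the axis
        assert coords[-1, 0, 2] - coords[0, 0, 2] == pytest.approx(40.8)
        radii = np.linalg.norm(coords[:, :, :2], axis=-1)
        assert radii == pytest.approx(9.0)


class TestDeterminism:
    def test_same_seed_same_scenario(self):
        a = build_scenario(ScenarioConfig(seed=42))
        b = build_scenario(ScenarioConfig(seed=42))
        assert a["truth"].sequence == b["truth"].sequence
        assert [c.label() for c in a["truth"].conjugates] == \
               [c.label() for c in b["truth"].conjugates]
        for pa, pb in zip(a["peaklists"], b["peaklists"]):
            assert pa.equals(pb)
        assert all(np.array_equal(a["hdx_truth"][k], b["hdx_truth"][k])
                   for k in a["hdx_truth"])

    def test_different_seeds_differ(self):
        a = build_scenario(ScenarioConfig(seed=1))
        b = build_scenario(ScenarioConfig(seed=2))
        assert a["truth"].sequence != b["truth"].sequence


class TestPlanting:
    def test_planted_pairs_within_span(self, scenario):
        truth = scenario["truth"]
        cfg = scenario["config"]
        linkers = {"DSG": DSG, "DSS": DSS}
        for cand, (a, b) in zip(truth.conjugates, truth.site_pairs):
            d = np.linalg.norm(truth.coords[a - cfg.protein_start]
                               - truth.coords[b - cfg.protein_start])
            lk = linkers[cand.linker]
            assert d <= lk.span + lk.span_tol

    def test_sites_lie_in_component_peptides(self, scenario):
        truth = scenario["truth"]
        for cand, (a, b) in zip(truth.conjugates, truth.site_pairs):
            spans = [(p.start, p.end) for p in cand.components]
            assert any(s <= a <= e for s, e in spans)
            assert any(s <= b <= e for s, e in spans)

    def test_zero_span_linker_plants_nothing(self):
        tiny = dataclasses.replace(DSG, name="tiny", span=0.1, span_tol=0.0)
        cfg = ScenarioConfig(seed=3)
        seq = random_protein(cfg)
        coords = gen_fold(dataclasses.replace(cfg, protein_sequence=seq))
        with pytest.warns(UserWarning, match="nothing planted"):
            conj, pairs, fr = plant_crosslinks(coords, seq, [tiny], cfg)
        assert conj == [] and pairs == [] and fr == []


class TestPeaklists:
    def test_noiseless_masses_exact(self, noiseless_scenario):
        truth = noiseless_scenario["truth"]
        peaks = noiseless_scenario["peaklists"][0]
        masses = peaks["mass"].to_numpy()
        for c in truth.conjugates:
            delta = doublet_delta(DSG if c.linker == "DSG" else DSS)
            assert np.min(np.abs(masses - c.mass)) < 1e-9
            assert np.min(np.abs(masses - (c.mass + delta))) < 1e-9

    def test_decoys_separated_by_min_ppm(self, scenario):
        truth = scenario["truth"]
        cfg = scenario["config"]
        true_masses = []
        for c in truth.conjugates:
            delta = doublet_delta(DSG if c.linker == "DSG" else DSS)
            true_masses += [c.mass, c.mass + delta]
        true_masses = np.asarray(true_masses)
        peaks = scenario["peaklists"][0]["mass"].to_numpy()
        # classify: anything further than 25 ppm from every truth is a decoy
        ppm = np.min(np.abs(peaks[:, None] - true_masses[None, :]) / true_masses, axis=1) * 1e6
        decoys = ppm[ppm > 25.0]
        assert len(decoys) == cfg.n_decoys
        assert decoys.min() >= cfg.decoy_min_ppm

    def test_expected_light_share_matches_fraction(self, noiseless_scenario):
        truth = noiseless_scenario["truth"]
        peaks = noiseless_scenario["peaklists"][0]
        lookup = {round(m, 6): i for m, i in zip(peaks["mass"], peaks["intensity"])}
        for c, f in zip(truth.conjugates, truth.mixing_fractions):
            delta = doublet_delta(DSG if c.linker == "DSG" else DSS)
            il = lookup[round(c.mass, 6)]
            ih = lookup[round(c.mass + delta, 6)]
            share = il / (il + ih)
            # lognormal noise cv=0.05: share stays near the planted fraction
            assert abs(share - f) < 0.1

    def test_replicate_count(self, scenario):
        assert len(scenario["peaklists"]) == scenario["config"].n_replicates


class TestHdxKinetics:
    def test_infinite_protection_gives_zero_uptake(self):
        u = residue_uptake_truth(np.array([1e12]), t=300.0, k_int=1.0)
        assert u[0] == pytest.approx(0.0, abs=1e-9)

    def test_long_time_saturates_to_one(self):
        u = residue_uptake_truth(np.array([1.0]), t=1e6, k_int=1.0)
        assert u[0] == pytest.approx(1.0)

    def test_nonpositive_protection_rejected(self):
        with pytest.raises(ValueError):
            residue_uptake_truth(np.array([0.0]), 1.0, 1.0)

    def test_protection_raised_only_inside_region(self):
        cfg = ScenarioConfig(seed=0)
        seq = random_protein(cfg)
        free, comp = protection_factors(cfg, seq)
        lo, hi = cfg.protected_region
        for i in range(len(seq)):
            pos = cfg.protein_start + i
            if lo <= pos <= hi:
                assert comp[i] == free[i] * cfg.protection_complex_factor
            else:
                assert comp[i] == free[i]

    def test_centroid_equals_control_plus_summed_uptake(self):
        cfg = ScenarioConfig(seed=6, hdx_noise_sd=0.0, n_replicates=1)
        seq = random_protein(cfg)
        records, controls, truth = gen_hdx(seq, cfg)
        from msbridge.hdx_analysis import exchangeable_positions
        for r in records[:50]:
            label = f"{r.peptide.sequence}({r.peptide.start}-{r.peptide.end})"
            u = truth[f"{r.state}@{r.timepoint}"]
            expected = controls[label] + sum(
                u[pos - cfg.protein_start] for pos in exchangeable_positions(r.peptide))
            assert r.centroid == pytest.approx(expected, abs=1e-9)


class TestWriteScenario:
    def test_directory_contents_and_manifest(self, tmp_path):
        cfg = ScenarioConfig(seed=8, n_replicates=2)
        write_scenario(tmp_path, cfg)
        for name in ("protein.fasta", "duplex.fasta", "peaklist_rep0.csv",
                     "peaklist_rep1.csv", "hdx_centroids.csv", "hdx_controls.csv",
                     "fold.pdb", "manifest.json"):
            assert (tmp_path / name).exists(), name
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["seed"] == 8
        assert manifest["protein_start"] == cfg.protein_start
        assert manifest["n_planted_conjugates"] == len(manifest["planted"])

    def test_default_duplex_strands(self):
        assert DEFAULT_FORWARD == "TTGGGTAAACAAG"
        assert DEFAULT_REVERSE == "CTTGTTTACCCAA"
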