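import numpy as np
import pytest

from emuflux.datasets import TCA_NETWORK_CSV
from emuflux.model import (ConfigError, build_stoichiometry, parse_config,
                           serialize_config)
from emuflux.fit import generate_initial_flux
from emuflux.measurements import load_measurements


class TestParseConfig:
    def test_tca_worksheet_structure(self):
        m = parse_config(TCA_NETWORK_CSV)
        assert len(m.reactions) == 16
        drains = [r.flux_id for r in m.reactions if r.kind == "biomass_drain"]
        assert drains == ["R8", "R9", "R10", "R11", "R12", "R13"]
        for fid in drains:
            assert m.reaction(fid).atom_map is None
        uptakes = [r.flux_id for r in m.reactions if r.kind == "substrate_input"]
        assert uptakes == ["R1", "R14"]

    def test_single_conversion_stoichiometry(self):
        m = parse_config("FluxID,Rxns,Net flux,Carbon_transitions\n"
                         "R1,A -> B,0,ab -> ab\n")
        S, mets = build_stoichiometry(m)
        assert mets == ["A", "B"]
        assert np.array_equal(S, [[-1.0], [1.0]])

    def test_condensation_reaction_parsed(self):
        m = parse_config(TCA_NETWORK_CSV)
        r3 = m.reaction("R3")
        assert [s for s, _ in r3.substrates] == ["ACCOA", "OAA"]
        assert [p for p, _ in r3.products] == ["IsoCit"]
        assert r3.atom_map.reactant_strings == ("ab", "cdef")
        assert r3.atom_map.product_strings == ("fedbac",)

    def test_reversible_pair_tags(self):
        m = parse_config(TCA_NETWORK_CSV)
        assert m.reaction("R6").pair_tag == m.reaction("R15").pair_tag == 1
        assert m.reaction("R7").pair_tag == m.reaction("R16").pair_tag == 2
        assert m.reaction("R2").pair_tag == 0

    def test_ascii_arrow_and_unicode_arrow_equivalent(self):
        a = parse_config("FluxID,Rxns,Net flux,Carbon_transitions\n"
                         "R1,A -> B,0,ab -> ab\n")
        b = parse_config("FluxID,Rxns,Net flux,Carbon_transitions\n"
                         "R1,A → B,0,ab → ab\n")
        assert serialize_config(a).equals(serialize_config(b))

    def test_atom_imbalance_rejected(self):
        with pytest.raises(ConfigError, match="R1"):
            parse_config("FluxID,Rxns,Net flux,Carbon_transitions\n"
                         "R1,A -> B,0,ab -> abc\n")

    def test_duplicate_flux_id_rejected(self):
        with pytest.raises(ConfigError, match="duplicate"):
            parse_config("FluxID,Rxns,Net flux,Carbon_transitions\n"
                         "R1,A -> B,0,ab -> ab\nR1,B -> C,0,ab -> ab\n")

    def test_carbon_count_conflict_rejected(self):
        with pytest.raises(ConfigError, match="carbons"):
            parse_config("FluxID,Rxns,Net flux,Carbon_transitions\n"
                         "R1,A -> B,0,ab -> ab\nR2,B -> C,0,abc -> abc\n")


class TestStoichiometry:
    def test_balanced_rows_exclude_special_roles(self, tca):
        mets = set(tca.model.balanced_metabolites)
        assert mets == {"PYR", "ACCOA", "IsoCit", "AKG", "Sym_SUC", "OAA"}
        for name in tca.model.metabolites:
            role = tca.model.role(name)
            if role.is_source or role.is_unbalanced or role.is_sink:
                assert name not in mets

    def test_random_feasible_flux_satisfies_balance(self, tca):
        v = generate_initial_flux(tca.model, seed=3)
        assert np.max(np.abs(tca.model.S @ v)) < 1e-9
        assert v.min() >= 0

    def test_cycle_rank_one_free_flux(self):
        m = parse_config("FluxID,Rxns,Net flux,Carbon_transitions\n"
                         "R1,A -> B,0,a -> a\nR2,B -> C,0,a -> a\n"
                         "R3,C -> A,0,a -> a\n")
        assert np.linalg.matrix_rank(m.S) == 2  # 3 reactions, 1 free loop flux

    def test_dead_end_warns(self):
        with pytest.warns(UserWarning, match="dead end"):
            parse_config("FluxID,Rxns,Net flux,Carbon_transitions\n"
                         "R1,A -> B,0,a -> a\n")


class TestRoundTrip:
    def test_serialize_parse_preserves_structure(self, tca):
        df = serialize_config(tca.model)
        again = parse_config(df)
        assert [r.flux_id for r in again.reactions] == tca.model.flux_ids
        for r1, r2 in zip(tca.model.reactions, again.reactions):
            assert r1.substrates == r2.substrates
            assert r1.products == r2.products
            assert r1.atom_map == r2.atom_map
            assert r1.kind == r2.kind

    def test_letter_conservation_every_parsed_reaction(self, tca):
        for r in tca.model.reactions:
            if r.atom_map is None:
                continue
            left = sorted("".join(r.atom_map.reactant_strings))
            right = sorted("".join(r.atom_map.product_strings))
            assert left == right


class TestLoadMeasurements:
    def _files(self, tmp_path, n, width=3):
        paths = []
        for k in range(n):
            p = tmp_path / f"Abundance_list_{k:03d}.csv"
            cols = ",".join(f"m{i}" for i in range(width))
            p.write_text(f"Fragment,{cols}\nfragA," +
                         ",".join(["0.2"] * width) + "\n")
            paths.append(p)
        return paths

    def test_time_series_sample_count(self, tmp_path):
        times = np.arange(17) * 5.0
        ms = load_measurements(self._files(tmp_path, 17), time_course=times)
        assert ms.n_samples == 17
        assert np.allclose(ms.times, times)

    def test_single_file_is_stationary(self, tmp_path):
        ms = load_measurements(self._files(tmp_path, 1))
        assert ms.times is None and ms.n_samples == 1

    def test_time_count_mismatch_fatal(self, tmp_path):
        with pytest.raises(ValueError, match="sampling times"):
            load_measurements(self._files(tmp_path, 3), time_course=[0.0, 5.0])

    def test_all_zero_spectrum_fatal(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("Fragment,m0,m1\nfragA,0,0\n")
        with pytest.raises(ValueError, match="degenerate"):
            load_measurements([p])

    def test_missing_composition_fatal(self, tmp_path):
        comp = tmp_path / "Components.csv"
        comp.write_text("Fragment,C,Skeleton_C\nother,2,2\n")
        with pytest.raises(ValueError, match="Components"):
            load_measurements(self._files(tmp_path, 1), components=comp)
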