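"""Fv pairing, antigen oligomer resolution, complex building, profiling."""

import itertools

import numpy as np
import pytest

from fvkit.annotation import detect_domains
from fvkit.fixtures import FixtureSpec, make_complex, make_fv
from fvkit.model import StructureMetadata
from fvkit.pipeline import standardize_entry
from fvkit.standardization import (AntigenUnit, build_antibody_units,
                                   build_complexes, classify_antigen_interfaces,
                                   count_cdr_contacts, pair_fv, profile_dataset,
                                   rename_antigen_chain, split_and_name)


class TestPairFv:
    def test_pair_below_cutoff(self, fv):
        domains = detect_domains(fv.model, fv.engine)
        pairs, singles = pair_fv(domains, fv.model)
        assert len(pairs) == 1 and not singles
        assert pairs[0].cys_distance == pytest.approx(15.0, abs=1e-6)

    def test_no_pair_above_cutoff(self):
        r = make_fv(FixtureSpec(seed=5, fv_separation=25.0))
        domains = detect_domains(r.model, r.engine)
        pairs, singles = pair_fv(domains, r.model)
        assert not pairs
        assert sorted(d.domain_type for d in singles) == ["VH", "VL"]

    def test_boundary_at_22(self):
        at = make_fv(FixtureSpec(seed=5, fv_separation=22.0))
        over = make_fv(FixtureSpec(seed=5, fv_separation=22.01))
        p_at, _ = pair_fv(detect_domains(at.model, at.engine), at.model)
        p_over, _ = pair_fv(detect_domains(over.model, over.engine), over.model)
        assert len(p_at) == 1       # "within a radius" includes the bound
        assert len(p_over) == 0

    def test_crossed_copies_match_brute_force(self):
        """2 VH + 2 VL: the greedy nearest-first matching agrees with the
        brute-force minimum-total-distance assignment."""
        r = make_fv(FixtureSpec(seed=5, n_fv=2))
        domains = detect_domains(r.model, r.engine)
        pairs, singles = pair_fv(domains, r.model)
        assert len(pairs) == 2 and not singles
        got = {(p.vh.chain_id, p.vl.chain_id) for p in pairs}

        vhs = [d for d in domains if d.domain_type == "VH"]
        vls = [d for d in domains if d.domain_type == "VL"]

        def cys_ca(dom, pos):
            rid = dom.original_of(pos)
            return r.model.chain(dom.chain_id).get(*rid).ca.coord

        best = None
        for perm in itertools.permutations(range(len(vls))):
            total = sum(np.linalg.norm(cys_ca(vhs[i], (92, ""))
                                       - cys_ca(vls[j], (88, "")))
                        for i, j in enumerate(perm))
            if best is None or total < best[0]:
                best = (total, {(vhs[i].chain_id, vls[j].chain_id)
                                for i, j in enumerate(perm)})
        assert got == best[1]

    def test_symmetric_under_input_order(self, fv):
        domains = detect_domains(fv.model, fv.engine)
        a, _ = pair_fv(domains, fv.model)
        b, _ = pair_fv(list(reversed(domains)), fv.model)
        assert {(p.vh.chain_id, p.vl.chain_id) for p in a} == \
               {(p.vh.chain_id, p.vl.chain_id) for p in b}

    def test_missing_cysteine_makes_domain_unpairable(self, fv):
        model = fv.model.copy()
        domains = detect_domains(model, fv.engine)
        vh = next(d for d in domains if d.domain_type == "VH")
        rid = vh.original_of((92, ""))
        res = model.chain(vh.chain_id).get(*rid)
        res.atoms = [a for a in res.atoms if a.name != "CA"]
        pairs, singles = pair_fv(domains, model)
        assert not pairs and len(singles) == 2


class TestAntigenInterfaces:
    def test_crystallographic_copies_stay_monomers(self):
        """Two antigen copies touching through a small patch (the
        crystal-contact scenario) are kept as separate monomer units."""
        c = make_complex(FixtureSpec(seed=7, target_contacts=5,
                                     crystal_copies=2, oligomer=False))
        units = classify_antigen_interfaces(c.model, c.antigen_chain_ids)
        assert len(units) == 2
        assert all(not u.oligomeric for u in units)

    def test_biological_dimer_merged(self):
        """A large antigen-antigen interface (the biological-dimer
        scenario) merges both chains into one oligomeric unit."""
        c = make_complex(FixtureSpec(seed=7, target_contacts=5,
                                     crystal_copies=2, oligomer=True))
        units = classify_antigen_interfaces(c.model, c.antigen_chain_ids)
        assert len(units) == 1
        assert units[0].oligomeric
        assert sorted(units[0].chain_ids) == sorted(c.antigen_chain_ids)

    def test_single_chain_is_monomer(self, complex_fixture):
        units = classify_antigen_interfaces(
            complex_fixture.model, complex_fixture.antigen_chain_ids)
        assert len(units) == 1 and not units[0].oligomeric

    def test_partition_property(self):
        c = make_complex(FixtureSpec(seed=7, target_contacts=5,
                                     crystal_copies=2, oligomer=False))
        units = classify_antigen_interfaces(c.model, c.antigen_chain_ids)
        covered = sorted(cid for u in units for cid in u.chain_ids)
        assert covered == sorted(c.antigen_chain_ids)

    def test_failing_classifier_falls_back_to_monomers(self):
        c = make_complex(FixtureSpec(seed=7, target_contacts=5,
                                     crystal_copies=2, oligomer=True))

        def broken(model, a, b):
            raise RuntimeError("boom")

        units = classify_antigen_interfaces(c.model, c.antigen_chain_ids,
                                            classifier=broken)
        assert len(units) == 2 and all(not u.oligomeric for u in units)


class TestBuildComplexes:
    def _units(self, fixture):
        domains = detect_domains(fixture.model, fixture.engine)
        return build_antibody_units(domains, fixture.model)

    def test_constructed_contact_count(self, complex_fixture):
        units = self._units(complex_fixture)
        antigen = AntigenUnit(complex_fixture.antigen_chain_ids)
        n = count_cdr_contacts(units[0], antigen, complex_fixture.model)
        assert n == complex_fixture.spec.target_contacts

    def test_contact_count_equals_brute_force(self, complex_fixture):
        """Fixture contact counting equals an all-pairs distance oracle."""
        model = complex_fixture.model
        units = self._units(complex_fixture)
        antigen = AntigenUnit(complex_fixture.antigen_chain_ids)
        cdr_cas = []
        for dom in units[0].domains:
            chain = model.chain(dom.chain_id)
            for res in chain:
                pos = dom.number_map.get(res.rid)
                if pos is not None and dom.cdrs.cdr_index(dom.domain_type, pos) is not None:
                    cdr_cas.append(res.ca.coord)
        ag_cas = [res.ca.coord for cid in antigen.chain_ids
                  for res in model.chain(cid)]
        brute = sum(1 for a in cdr_cas for b in ag_cas
                    if float(np.linalg.norm(a - b)) < 7.5)
        assert count_cdr_contacts(units[0], antigen, model) == brute

    def test_remote_antigen_gives_free_antibody(self, fv):
        units = self._units(fv)
        # no antigen units at all -> free antibody record
        records = build_complexes(units, [], fv.model)
        assert len(records) == 1
        assert records[0].antigen is None

    def test_short_antigen_excluded(self):
        c = make_complex(FixtureSpec(seed=9, target_contacts=5,
                                     antigen_length=40))
        units = self._units(c)
        antigens = [AntigenUnit(c.antigen_chain_ids)]
        records = build_complexes(units, antigens, c.model)
        assert len(records) == 1
        assert records[0].antigen is None  # 40 <= 50: complex subset excludes

    def test_exactly_50_excluded_51_kept(self):
        """'More than 50 residues' is strict."""
        at50 = make_complex(FixtureSpec(seed=9, target_contacts=5,
                                        antigen_length=50))
        at51 = make_complex(FixtureSpec(seed=9, target_contacts=5,
                                        antigen_length=51))
        for fixture, kept in ((at50, False), (at51, True)):
            units = self._units(fixture)
            records = build_complexes(units,
                                      [AntigenUnit(fixture.antigen_chain_ids)],
                                      fixture.model)
            assert (records[0].antigen is not None) == kept

    def test_every_unit_appears_exactly_once_when_free(self):
        r = make_fv(FixtureSpec(seed=11, n_fv=3))
        units = self._units(r)
        records = build_complexes(units, [], r.model)
        assert len(records) == len(units) == 3


class TestSplitAndName:
    def test_two_crystal_copies_two_files(self):
        """Crystal-contact copies produce XXXX_1 and XXXX_2, one antigen
        chain each."""
        c = make_complex(FixtureSpec(seed=7, target_contacts=5,
                                     crystal_copies=2, oligomer=False))
        outs, outcome = standardize_entry(c.model, c.engine)
        names = [n for n, _ in outs]
        assert names == ["9FIX_1", "9FIX_2"]
        for _, m in outs:
            antigen_chains = [c_ for c_ in m.chain_ids if c_ not in ("H", "L")]
            assert len(antigen_chains) == 1

    def test_oligomer_kept_in_both_files(self):
        c = make_complex(FixtureSpec(seed=7, target_contacts=5,
                                     crystal_copies=2, oligomer=True))
        outs, _ = standardize_entry(c.model, c.engine)
        assert len(outs) == 2
        for _, m in outs:
            antigen_chains = [c_ for c_ in m.chain_ids if c_ not in ("H", "L")]
            assert len(antigen_chains) == 2

    def test_free_antibody_named_1(self, fv):
        outs, _ = standardize_entry(fv.model, fv.engine)
        assert [n for n, _ in outs] == ["9FIX_1"]

    def test_deterministic_rerun(self):
        c1 = make_complex(FixtureSpec(seed=7, target_contacts=5,
                                      crystal_copies=2))
        c2 = make_complex(FixtureSpec(seed=7, target_contacts=5,
                                      crystal_copies=2))
        outs1, _ = standardize_entry(c1.model, c1.engine)
        outs2, _ = standardize_entry(c2.model, c2.engine)
        assert [n for n, _ in outs1] == [n for n, _ in outs2]
        assert [m.chain_ids for _, m in outs1] == [m.chain_ids for _, m in outs2]

    def test_antibody_chains_renamed_and_martin_numbered(self, standardized_ref):
        assert standardized_ref.chain_ids[:2] == ["H", "L"]
        h_numbers = [r.seq_number for r in standardized_ref.chain("H")]
        assert h_numbers[0] == 25 and h_numbers[-1] == 105  # Martin range

    def test_scfv_split_into_h_and_l(self):
        r = make_fv(FixtureSpec(seed=3, scfv=True))
        outs, _ = standardize_entry(r.model, r.engine)
        assert len(outs) == 1
        assert outs[0][1].chain_ids == ["h", "l"]


class TestRenameAntigen:
    def test_h_renamed_to_a(self):
        assert rename_antigen_chain("H", {"H", "L"}) == "A"

    def test_unrelated_id_kept(self):
        assert rename_antigen_chain("C", {"H", "L"}) == "C"

    def test_collision_fallback_deterministic(self):
        taken = {"H", "L", "A"}
        assert rename_antigen_chain("L", set(taken)) == "B"
        assert rename_antigen_chain("L", set(taken)) == "B"


class TestProfile:
    def test_method_percentages(self):
        metas = [StructureMetadata("xray", 2.0)] * 3 + [StructureMetadata("em", 3.5)]
        p = profile_dataset(metas)
        assert p.method_percent["xray"] == pytest.approx(75.0)
        assert p.method_percent["em"] == pytest.approx(25.0)

    def test_fraction_below_cutoff_all(self):
        metas = [StructureMetadata("xray", 2.0), StructureMetadata("xray", 3.0)]
        assert profile_dataset(metas, 4.0).fraction_below_cutoff == pytest.approx(1.0)

    def test_fraction_and_mean(self):
        metas = [StructureMetadata("xray", 2.0), StructureMetadata("xray", 4.5)]
        p = profile_dataset(metas, 4.0)
        assert p.fraction_below_cutoff == pytest.approx(0.5)
        assert p.method_mean_resolution["xray"] == pytest.approx(3.25)

    def test_missing_resolution_counted_separately(self):
        metas = [StructureMetadata("xray", 2.0), StructureMetadata("nmr", None)]
        p = profile_dataset(metas, 4.0)
        assert p.n_without_resolution == 1
        assert p.fraction_below_cutoff == pytest.approx(1.0)
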