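import numpy as np
import pytest

from zernab.fixtures import make_toy_complex
from zernab.patches import (
    DecoyParams, SurfacePatch, cdr_patch, electrostatic_extension,
    generate_decoys, interface_centerpoint, native_epitope, pivot_residue,
    shell_patch,
)
from zernab.structure_io import Atom, Structure, assign_chain_roles
from zernab.surface import residue_sasa, sample_sas


def _chain(chain_id, numbers, z=0.0, spacing=4.0, radius=1.9, names=None):
    atoms = []
    for i, num in enumerate(numbers):
        atoms.append(Atom(serial=i + 1, name="CA", element="C",
                          position=np.array([spacing * i, 0.0, z]),
                          radius=radius, partial_charge=0.0,
                          residue_key=(chain_id, num, ""), residue_name="ALA"))
    return atoms


class TestCDRPatch:
    def test_patch_covers_exactly_the_h1_residues(self):
        s = Structure(atoms=_chain("H", [20, 21, 26, 27, 28, 40, 41]))
        s = assign_chain_roles(s, heavy="H")
        cloud = sample_sas(s)
        with pytest.warns(UserWarning, match="light"):
            patch = cdr_patch(s, cloud)
        assert patch.residues == {("H", 26, ""), ("H", 27, ""), ("H", 28, "")}
        in_range = sum(1 for k in cloud.residue_keys if k in patch.residues)
        assert len(patch) == in_range

    def test_insertion_coded_residue_belongs_to_its_loop(self):
        atoms = _chain("H", [95, 96, 97])
        atoms.append(Atom(serial=9, name="CA", element="C",
                          position=np.array([4.0, 4.0, 0.0]), radius=1.9,
                          partial_charge=0.0, residue_key=("H", 100, "A"),
                          residue_name="ALA"))
        s = assign_chain_roles(Structure(atoms=atoms), heavy="H")
        with pytest.warns(UserWarning):
            patch = cdr_patch(s, sample_sas(s))
        assert ("H", 100, "A") in patch.residues

    def test_non_chothia_numbering_is_an_error(self):
        s = Structure(atoms=_chain("H", [200, 201, 202]))
        s = assign_chain_roles(s, heavy="H")
        cloud = sample_sas(s)
        with pytest.raises(ValueError, match="Chothia"), pytest.warns(UserWarning):
            cdr_patch(s, cloud)

    def test_toy_complex_finds_all_designated_cdr_residues(self, toy):
        patch = cdr_patch(toy["structure"], toy["antibody_cloud"])
        assert len({k for k in patch.residues if k[0] == "H"}) == 20
        assert len({k for k in patch.residues if k[0] == "L"}) == 27


class TestNativeEpitope:
    def test_distant_chains_give_no_contact_error(self):
        atoms = _chain("H", [26, 27]) + [
            Atom(serial=10 + i, name="CA", element="C",
                 position=np.array([100.0 + 4 * i, 0, 0]), radius=1.9,
                 partial_charge=0.0, residue_key=("A", i + 1, ""),
                 residue_name="ALA") for i in range(3)]
        s = assign_chain_roles(Structure(atoms=atoms), heavy="H", antigen=["A"])
        ag_cloud = sample_sas(s.subset(["A"]))
        with pytest.raises(ValueError, match="no contact"):
            native_epitope(s, ag_cloud, cutoff=6.0)

    def test_single_residue_in_range(self):
        atoms = _chain("H", [26]) + [
            Atom(serial=2, name="CA", element="C", position=np.array([5.0, 0, 0]),
                 radius=1.9, partial_charge=0.0, residue_key=("A", 1, ""),
                 residue_name="ALA"),
            Atom(serial=3, name="CA", element="C", position=np.array([30.0, 0, 0]),
                 radius=1.9, partial_charge=0.0, residue_key=("A", 2, ""),
                 residue_name="ALA")]
        s = assign_chain_roles(Structure(atoms=atoms), heavy="H", antigen=["A"])
        patch = native_epitope(s, sample_sas(s.subset(["A"])), cutoff=6.0)
        assert patch.residues == {("A", 1, "")}
        assert patch.pivot == ("A", 1, "")

    def test_matches_brute_force_distance_scan(self, toy):
        s = toy["structure"]
        patch = toy["native"]
        ab = [a for a in s.atoms if a.residue_key[0] in "HL"]
        expected = set()
        for a in s.atoms:
            if a.residue_key[0] != "A":
                continue
            dmin = min(np.linalg.norm(a.position - b.position) for b in ab)
            if dmin < 6.0:
                expected.add(a.residue_key)
        assert patch.residues == expected

    def test_monotone_in_cutoff(self, toy):
        small = native_epitope(toy["structure"], toy["antigen_cloud"], cutoff=6.0)
        large = native_epitope(toy["structure"], toy["antigen_cloud"], cutoff=15.0,
                               kind="epitope_elec")
        assert small.residues <= large.residues


class TestPivotResidue:
    def _patch_of(self, structure, keys):
        cloud = sample_sas(structure)
        mask = np.array([k in keys for k in cloud.residue_keys])
        return SurfacePatch(positions=cloud.positions[mask],
                            es_values=cloud.es_values[mask],
                            residue_keys=[k for k, m in
                                          zip(cloud.residue_keys, mask) if m],
                            kind="epitope_geom", pivot=("", 0, "tmp"))

    def test_single_residue_patch(self):
        s = Structure(atoms=_chain("A", [1]))
        p = self._patch_of(s, {("A", 1, "")})
        assert pivot_residue(p, s) == ("A", 1, "")

    def test_middle_of_three_collinear(self):
        s = Structure(atoms=_chain("A", [1, 2, 3], spacing=5.0))
        p = self._patch_of(s, {("A", i, "") for i in (1, 2, 3)})
        assert pivot_residue(p, s) == ("A", 2, "")

    def test_matches_exhaustive_mean_distance(self):
        rng = np.random.default_rng(21)
        atoms = [Atom(serial=i + 1, name="CA", element="C",
                      position=rng.uniform(-12, 12, 3), radius=1.9,
                      partial_charge=0.0, residue_key=("A", i + 1, ""),
                      residue_name="ALA") for i in range(8)]
        s = Structure(atoms=atoms)
        p = self._patch_of(s, {a.residue_key for a in atoms})
        pos = {a.residue_key: a.position for a in atoms}
        keys = sorted(pos)
        means = {k: np.mean([np.linalg.norm(pos[k] - pos[j]) for j in keys])
                 for k in keys}
        assert pivot_residue(p, s) == min(means, key=means.get)


class TestDecoys:
    def test_every_decoy_satisfies_the_three_constraints(self, toy):
        params = DecoyParams()
        sasa = toy["antigen_sasa"]
        native = toy["native"]
        native_sasa = sum(sasa[k] for k in native.residues)
        lo, hi = params.pivot_window
        for seed in (1, 2):
            decoys = generate_decoys(toy["antigen"], toy["antigen_cloud"], native,
                                     params, n_decoys=8, seed=seed)
            assert len(decoys) == 8
            for d in decoys:
                assert lo <= sasa[d.pivot] <= hi
                assert sum(sasa[k] for k in d.residues) >= native_sasa
                assert d.overlap_with_native <= params.max_overlap

    def test_deterministic_under_seed(self, toy):
        kw = dict(native=toy["native"], n_decoys=4, seed=9)
        d1 = generate_decoys(toy["antigen"], toy["antigen_cloud"], **kw)
        d2 = generate_decoys(toy["antigen"], toy["antigen_cloud"], **kw)
        assert [d.residues for d in d1] == [d.residues for d in d2]

    def test_forced_pivot_when_window_admits_one_residue(self, toy):
        sasa = toy["antigen_sasa"]
        shell = {k: v for k, v in sasa.items() if k[1] != 999}
        # pick the residue whose SASA is farthest from every other (sampling
        # quantisation can tie values exactly, which would leave no window)
        gaps = {k: min(abs(shell[j] - shell[k]) for j in shell if j != k)
                for k in shell}
        target = max(gaps, key=gaps.get)
        assert gaps[target] > 0
        params = DecoyParams(pivot_sasa_mean=shell[target],
                             pivot_sasa_sd=0.9 * gaps[target],
                             pivot_window_halfwidth=0.5)
        decoys = generate_decoys(toy["antigen"], toy["antigen_cloud"],
                                 toy["native"], params, n_decoys=3, seed=1)
        assert all(d.pivot == target for d in decoys)

    def test_native_covering_whole_surface_is_infeasible(self, toy):
        cloud = toy["antigen_cloud"]
        whole = SurfacePatch(positions=cloud.positions, es_values=cloud.es_values,
                             residue_keys=list(cloud.residue_keys),
                             kind="epitope_geom", pivot=toy["native"].pivot)
        params = DecoyParams(max_overlap=1e-9)
        with pytest.raises((RuntimeError, ValueError)):
            generate_decoys(toy["antigen"], cloud, whole, params,
                            n_decoys=1, seed=0, max_attempts=25)

    def test_unavoidable_overlap_exhausts_resampling_budget(self, toy):
        # native = every growable residue: a SASA-matched decoy must include
        # them all, so with a tiny overlap cap each attempt is rejected
        from zernab.surface import relative_sasa

        cloud = toy["antigen_cloud"]
        rsasa = relative_sasa(toy["antigen"])
        growable = {k for k, r in rsasa.items() if r > 0.2} & set(cloud.residue_keys)
        mask = np.array([k in growable for k in cloud.residue_keys])
        native = SurfacePatch(positions=cloud.positions[mask],
                              es_values=cloud.es_values[mask],
                              residue_keys=[k for k, m in
                                            zip(cloud.residue_keys, mask) if m],
                              kind="epitope_geom", pivot=sorted(growable)[0])
        params = DecoyParams(max_overlap=1e-9)
        with pytest.raises(RuntimeError, match="attempts"):
            generate_decoys(toy["antigen"], cloud, native, params,
                            n_decoys=1, seed=0, max_attempts=20)

    def test_unreachable_target_sasa_is_an_error(self, toy):
        cloud = toy["antigen_cloud"]
        native = toy["native"]
        huge = SurfacePatch(positions=native.positions, es_values=native.es_values,
                            residue_keys=list(native.residue_keys),
                            kind="epitope_geom", pivot=native.pivot)
        params = DecoyParams(rsasa_min=0.99)  # nothing is growable enough
        with pytest.raises(ValueError, match="too small|pivot window"):
            generate_decoys(toy["antigen"], cloud, huge, params,
                            n_decoys=1, seed=0)


class TestElectrostaticExtension:
    def test_zero_radius_keeps_residues(self, toy):
        d = generate_decoys(toy["antigen"], toy["antigen_cloud"], toy["native"],
                            n_decoys=1, seed=3)[0]
        ext = electrostatic_extension(d, toy["antigen"], toy["antigen_cloud"],
                                      radius=1e-9)
        assert ext.residues == d.residues
        assert ext.kind == "decoy_elec"

    def test_huge_radius_includes_every_residue(self, toy):
        d = generate_decoys(toy["antigen"], toy["antigen_cloud"], toy["native"],
                            n_decoys=1, seed=3)[0]
        ext = electrostatic_extension(d, toy["antigen"], toy["antigen_cloud"],
                                      radius=1e6)
        surface_residues = set(toy["antigen_cloud"].residue_keys)
        assert ext.residues == surface_residues | d.residues

    def test_matches_distance_scan(self, toy):
        d = generate_decoys(toy["antigen"], toy["antigen_cloud"], toy["native"],
                            n_decoys=1, seed=4)[0]
        radius = 15.0
        ext = electrostatic_extension(d, toy["antigen"], toy["antigen_cloud"],
                                      radius=radius)
        ag = toy["antigen"]
        pos = {a.residue_key: a.position for a in ag.atoms}  # single-atom residues
        pivot_pos = pos[d.pivot]
        expected = {k for k, p in pos.items()
                    if np.linalg.norm(p - pivot_pos) <= radius}
        expected = (expected & set(toy["antigen_cloud"].residue_keys)) | d.residues
        assert ext.residues == expected


class TestShellPatch:
    def test_fraction_one_is_identity(self, toy):
        cdr = cdr_patch(toy["structure"], toy["antibody_cloud"])
        b = interface_centerpoint(toy["structure"])
        full = shell_patch(cdr, b, 1.0)
        assert len(full) == len(cdr)
        np.testing.assert_array_equal(np.sort(full.positions, axis=0),
                                      np.sort(cdr.positions, axis=0))

    def test_fraction_selects_nearest_points(self, toy):
        cdr = cdr_patch(toy["structure"], toy["antibody_cloud"])
        b = interface_centerpoint(toy["structure"])
        sub = shell_patch(cdr, b, 0.2)
        assert len(sub) == int(np.ceil(0.2 * len(cdr)))
        d_in = np.linalg.norm(sub.positions - b, axis=1)
        all_d = np.linalg.norm(cdr.positions - b, axis=1)
        excluded = np.sort(all_d)[len(sub):]
        assert d_in.max() <= excluded.min() + 1e-12

    def test_shells_nest_monotonically(self, toy):
        cdr = cdr_patch(toy["structure"], toy["antibody_cloud"])
        b = interface_centerpoint(toy["structure"])
        prev = None
        for frac in (0.1, 0.3, 0.6, 1.0):
            pts = {tuple(p) for p in shell_patch(cdr, b, frac).positions}
            if prev is not None:
                assert prev <= pts
            prev = pts

    def test_centerpoint_between_two_lobes(self):
        lobe1 = _chain("H", [26, 27], z=0.0)
        lobe2 = [Atom(serial=10 + i, name="CA", element="C",
                      position=np.array([4.0 * i, 10.0, 0.0]), radius=1.9,
                      partial_charge=0.0, residue_key=("L", 24 + i, ""),
                      residue_name="ALA") for i in range(2)]
        antigen = [Atom(serial=20, name="CA", element="C",
                        position=np.array([2.0, 5.0, 8.0]), radius=1.9,
                        partial_charge=0.0, residue_key=("A", 1, ""),
                        residue_name="ALA")]
        s = assign_chain_roles(Structure(atoms=lobe1 + lobe2 + antigen),
                               heavy="H", light="L", antigen=["A"])
        b = interface_centerpoint(s, n_atoms=4)
        expected = np.mean([a.position for a in lobe1 + lobe2], axis=0)
        np.testing.assert_allclose(b, expected, atol=1e-12)

    def test_bad_fraction_raises(self, toy):
        cdr = cdr_patch(toy["structure"], toy["antibody_cloud"])
        b = interface_centerpoint(toy["structure"])
        for frac in (0.0, -0.2, 1.2):
            with pytest.raises(ValueError):
                shell_patch(cdr, b, frac)
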