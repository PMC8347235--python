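"""Feature perception, hypothesis generation and 3D screening."""

import itertools

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy.spatial.transform import Rotation

from mmpscreen.pharmacophore import (
    Feature,
    Hypothesis,
    PharmacophorePose,
    Site,
    generate_epharmacophore,
    generate_ligand_hypothesis,
    parse_hypothesis_string,
    perceive_features,
    screen_flexible,
    screen_inplace,
    validate_and_select,
)
from mmpscreen import fixtures as fx


def embed(smiles, seed=7):
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    AllChem.EmbedMolecule(mol, randomSeed=seed)
    return Chem.RemoveHs(mol)


def brute_force_match(sites, feats, min_optional, tolerance_default=2.0):
    """Exhaustive injective site->feature assignment oracle."""
    n_s = len(sites)
    choices = []
    for site in sites:
        tol = site.tolerance or tolerance_default
        ok = [
            j
            for j, f in enumerate(feats)
            if f.kind == site.kind
            and np.linalg.norm(f.position - site.position) <= tol
        ]
        choices.append((site.required, ok))
    sets = [
        (c + [None]) if not req else c for req, c in choices
    ]
    for combo in itertools.product(*sets):
        used = [c for c in combo if c is not None]
        if len(set(used)) != len(used):
            continue
        n_opt = sum(
            1
            for (req, _), c in zip(choices, combo)
            if not req and c is not None
        )
        if n_opt >= min_optional:
            return True
    return False


class TestPerceiveFeatures:
    def test_benzene_single_ring_centroid(self):
        mol = embed("c1ccccc1")
        feats = perceive_features(mol)
        rings = [f for f in feats if f.kind == "R"]
        assert len(rings) == 1
        carbons = mol.GetConformer().GetPositions()
        assert np.allclose(rings[0].position, carbons.mean(axis=0),
                           atol=1e-9)

    def test_acetate_negative_and_two_acceptors(self):
        feats = perceive_features(embed("CC(=O)[O-]"))
        kinds = sorted(f.kind for f in feats)
        assert kinds.count("N") == 1
        assert kinds.count("A") == 2
        neg = next(f for f in feats if f.kind == "N")
        match_atoms = neg.atom_indices
        pos = embed("CC(=O)[O-]").GetConformer().GetPositions()
        assert np.allclose(
            neg.position, pos[list(match_atoms)].mean(axis=0), atol=1e-9
        )

    def test_methane_has_no_polar_features(self):
        feats = perceive_features(embed("C"))
        assert all(f.kind not in "ADRN" for f in feats)

    def test_deterministic(self):
        mol = embed("O=S(=O)(Nc1ccccc1C(=O)O)c1ccccc1")
        f1 = perceive_features(mol)
        f2 = perceive_features(mol)
        assert [(a.kind, a.atom_indices) for a in f1] == [
            (b.kind, b.atom_indices) for b in f2
        ]
        for a, b in zip(f1, f2):
            assert np.array_equal(a.position, b.position)


class TestParseHypothesisString:
    def test_three_required_sites(self):
        h = parse_hypothesis_string("A (+) A (+) R (+)")
        assert [s.kind for s in h.sites] == ["A", "A", "R"]
        assert all(s.required for s in h.sites)

    def test_mixed_required_and_optional(self):
        h = parse_hypothesis_string("A (+) A (−) D (−) D (−) D (−) D (−) R (+)")
        assert len(h.sites) == 7
        assert h.n_required == 2
        required_kinds = [s.kind for s in h.sites if s.required]
        assert required_kinds == ["A", "R"]

    def test_hydrophobic_token_accepted(self):
        h = parse_hypothesis_string("A (−) A(+) D (−) D (−) H (−) N (+) R (−) R (−)")
        assert len(h.sites) == 8
        assert "H" in {s.kind for s in h.sites}

    def test_empty_string_rejected(self):
        with pytest.raises(ValueError):
            parse_hypothesis_string("")

    def test_unknown_kind_named_in_error(self):
        with pytest.raises(ValueError, match="X"):
            parse_hypothesis_string("A (+) X (+)")


class TestScreenInplace:
    def test_within_tolerance_matches(self):
        hyp = Hypothesis(
            "h",
            [
                Site("A", np.array([0.0, 0, 0]), 2.0, True),
                Site("R", np.array([5.0, 0, 0]), 2.0, True),
            ],
        )
        pose = PharmacophorePose(
            "p", "c",
            [Feature("A", [0.5, 0, 0]), Feature("R", [5.1, 0, 0])],
        )
        matches = screen_inplace(hyp, [pose])
        assert len(matches) == 1
        assert matches[0].rmsd < 0.6

    def test_outside_tolerance_rejected(self):
        hyp = Hypothesis(
            "h",
            [
                Site("A", np.array([0.0, 0, 0]), 2.0, True),
                Site("R", np.array([5.0, 0, 0]), 2.0, True),
            ],
        )
        pose = PharmacophorePose(
            "p", "c",
            [Feature("A", [0.5, 0, 0]), Feature("R", [7.5, 0, 0])],
        )
        assert screen_inplace(hyp, [pose]) == []

    def test_site_without_coordinates_rejected(self):
        hyp = parse_hypothesis_string("A (+)")
        pose = PharmacophorePose("p", "c", [Feature("A", [0, 0, 0])])
        with pytest.raises(ValueError):
            screen_inplace(hyp, [pose])

    def test_assignment_is_injective(self):
        # one A feature cannot satisfy two A sites
        hyp = Hypothesis(
            "h",
            [
                Site("A", np.array([0.0, 0, 0]), 2.0, True),
                Site("A", np.array([1.0, 0, 0]), 2.0, True),
            ],
        )
        pose = PharmacophorePose("p", "c", [Feature("A", [0.5, 0, 0])])
        assert screen_inplace(hyp, [pose]) == []

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(7)
        kinds = "ADRN"
        agree = 0
        n_trials = 1000
        for _ in range(n_trials):
            n_s = int(rng.integers(1, 5))
            n_f = int(rng.integers(0, 9))
            sites = [
                Site(
                    kinds[int(rng.integers(len(kinds)))],
                    rng.uniform(0, 8, 3),
                    float(rng.uniform(1.0, 3.0)),
                    bool(rng.random() < 0.7),
                )
                for _ in range(n_s)
            ]
            n_opt_sites = sum(1 for s in sites if not s.required)
            min_opt = int(rng.integers(0, n_opt_sites + 1))
            hyp = Hypothesis("h", sites, min_optional_matches=min_opt)
            feats = [
                Feature(
                    kinds[int(rng.integers(len(kinds)))], rng.uniform(0, 8, 3)
                )
                for _ in range(n_f)
            ]
            pose = PharmacophorePose("p", "c", feats)
            got = len(screen_inplace(hyp, [pose])) == 1
            want = brute_force_match(sites, feats, min_opt)
            if got == want:
                agree += 1
        assert agree == n_trials

    def test_planted_pose_labels_recovered(self):
        hyp = fx.make_random_hypothesis("AADR", seed=2)
        poses, labels = fx.make_planted_pose_set(hyp, 25, 25, seed=9)
        matched = {m.pose_id for m in screen_inplace(hyp, poses)}
        expected = {p.pose_id for p, keep in zip(poses, labels) if keep}
        assert matched == expected


class TestScreenFlexible:
    def _hyp(self):
        return fx.make_random_hypothesis("ADRN", seed=5)

    def test_rigid_motion_invariance(self):
        hyp = self._hyp()
        pts = np.stack([s.position for s in hyp.sites])
        R = Rotation.from_euler("xyz", [90, 30, 10], degrees=True).as_matrix()
        moved = (R @ pts.T).T + np.array([5.0, -3.0, 2.0])
        pose = PharmacophorePose(
            "p", "c",
            [Feature(s.kind, x) for s, x in zip(hyp.sites, moved)],
        )
        res = screen_flexible(hyp, {"c": [pose]})
        assert len(res) == 1
        assert res[0].rmsd == pytest.approx(0.0, abs=1e-9)

    def test_mirror_image_of_chiral_sites_rejected(self):
        # a strongly chiral labeled tetrahedron: reflection cannot be
        # reproduced by any proper rotation within the tight tolerance
        sites = [
            Site("A", np.array([0.0, 0.0, 0.0]), 0.75, True),
            Site("D", np.array([6.0, 0.0, 0.0]), 0.75, True),
            Site("R", np.array([0.0, 6.0, 0.0]), 0.75, True),
            Site("N", np.array([0.0, 0.0, 6.0]), 0.75, True),
        ]
        hyp = Hypothesis("chiral", sites)
        mirrored = np.stack([s.position for s in sites]) * [-1, 1, 1]
        pose = PharmacophorePose(
            "p", "c",
            [Feature(s.kind, x) for s, x in zip(sites, mirrored)],
        )
        assert screen_flexible(hyp, {"c": [pose]}) == []
        # sanity: the unreflected copy matches exactly
        good = PharmacophorePose(
            "p2", "c2",
            [Feature(s.kind, s.position.copy()) for s in sites],
        )
        assert len(screen_flexible(hyp, {"c2": [good]})) == 1

    def test_empty_conformer_list_omits_compound(self):
        hyp = self._hyp()
        res = screen_flexible(hyp, {"c": []})
        assert res == []

    def test_conformer_cap_respected(self):
        hyp = self._hyp()
        pts = np.stack([s.position for s in hyp.sites])
        good = PharmacophorePose(
            "pgood", "c", [Feature(s.kind, x) for s, x in zip(hyp.sites, pts)]
        )
        # tripling internal distances defeats any rigid superposition
        bad = PharmacophorePose(
            "pbad", "c",
            [Feature(s.kind, x * 3.0) for s, x in zip(hyp.sites, pts)],
        )
        # good conformer is 11th: ignored when at most 10 are considered
        res = screen_flexible(hyp, {"c": [bad] * 10 + [good]},
                              max_conformers=10)
        assert res == []
        res = screen_flexible(hyp, {"c": [bad] * 9 + [good]},
                              max_conformers=10)
        assert len(res) == 1


class TestGenerateEpharmacophore:
    def test_planted_two_cluster_geometry(self, rng):
        poses = []
        for i in range(20):
            poses.append(
                PharmacophorePose(
                    f"f{i}", f"f{i}",
                    [
                        Feature("A", rng.normal(0, 0.15, 3)),
                        Feature("R", np.array([5.0, 0, 0])
                                + rng.normal(0, 0.15, 3)),
                    ],
                    score=float(-rng.uniform(1, 10)),
                )
            )
        hyps = generate_epharmacophore(poses, n_clusters=2, max_sites=2)
        best = hyps[-1]
        assert len(best.sites) == 2
        by_kind = {s.kind: s for s in best.sites}
        assert np.linalg.norm(by_kind["A"].position) < 0.5
        assert np.linalg.norm(by_kind["R"].position - [5, 0, 0]) < 0.5

    def test_identical_poses_give_exact_sites(self):
        feats = [Feature("A", [1.0, 2.0, 3.0]), Feature("D", [4.0, 5.0, 6.0])]
        poses = [
            PharmacophorePose(f"p{i}", f"p{i}", list(feats), score=-5.0)
            for i in range(5)
        ]
        hyps = generate_epharmacophore(poses, n_clusters=2, max_sites=2)
        positions = sorted(
            tuple(np.round(s.position, 9)) for s in hyps[-1].sites
        )
        assert positions == [(1.0, 2.0, 3.0), (4.0, 5.0, 6.0)]

    def test_max_sites_one_keeps_best_scored_cluster(self):
        strong = PharmacophorePose(
            "s", "s", [Feature("A", [0.0, 0, 0])], score=-10.0
        )
        weak = PharmacophorePose(
            "w", "w", [Feature("D", [5.0, 0, 0])], score=-1.0
        )
        hyps = generate_epharmacophore(
            [strong, weak], n_clusters=2, max_sites=1
        )
        assert len(hyps) == 1
        assert hyps[0].sites[0].kind == "A"

    def test_too_few_features_warns_and_shrinks(self):
        poses = [
            PharmacophorePose("p", "p", [Feature("A", [0.0, 0, 0])],
                              score=-2.0)
        ]
        with pytest.warns(UserWarning):
            hyps = generate_epharmacophore(poses, n_clusters=15, max_sites=8)
        assert len(hyps) == 1

    def test_unscored_pose_rejected(self):
        poses = [PharmacophorePose("p", "p", [Feature("A", [0.0, 0, 0])])]
        with pytest.raises(ValueError):
            generate_epharmacophore(poses)


class TestGenerateLigandHypothesis:
    def _planted_actives(self, seed=11, n=4):
        tri = fx.make_random_hypothesis("AAR", seed=seed)
        pts = np.stack([s.position for s in tri.sites])
        rng = np.random.default_rng(seed)
        actives = {}
        for i in range(n):
            R = Rotation.random(random_state=int(rng.integers(10**6)))
            moved = (R.as_matrix() @ pts.T).T + rng.uniform(-5, 5, 3)
            actives[f"act{i}"] = [
                PharmacophorePose(
                    f"a{i}", f"act{i}",
                    [Feature(s.kind, x) for s, x in zip(tri.sites, moved)],
                )
            ]
        return actives

    def test_shared_triangle_recovered(self):
        actives = self._planted_actives()
        hyps = generate_ligand_hypothesis(
            actives, min_active_fraction=0.5, n_features=(3, 3)
        )
        assert hyps
        assert sorted(s.kind for s in hyps[0].sites) == ["A", "A", "R"]
        rescreen = screen_flexible(hyps[0], actives)
        assert len(rescreen) == len(actives)

    def test_full_fraction_on_planted_set(self):
        actives = self._planted_actives()
        hyps = generate_ligand_hypothesis(
            actives, min_active_fraction=1.0, n_features=(3, 3)
        )
        assert hyps
        matched = screen_flexible(hyps[0], actives)
        assert {m.compound_id for m in matched} == set(actives)

    def test_no_shared_arrangement_gives_empty(self, rng):
        actives = {}
        kinds_cycle = ["AAD", "RRN", "DNR"]
        for i, kinds in enumerate(kinds_cycle):
            feats = [
                Feature(k, rng.uniform(0, 30, 3)) for k in kinds
            ]
            actives[f"act{i}"] = [
                PharmacophorePose(f"a{i}", f"act{i}", feats)
            ]
        with pytest.warns(UserWarning):
            hyps = generate_ligand_hypothesis(
                actives, min_active_fraction=1.0, n_features=(3, 3)
            )
        assert hyps == []

    def test_self_consistency_property(self):
        # every emitted hypothesis satisfies its own matching quota
        actives = self._planted_actives(seed=21, n=5)
        frac = 0.6
        hyps = generate_ligand_hypothesis(
            actives, min_active_fraction=frac, n_features=(3, 3)
        )
        for hyp in hyps[:3]:
            matched = {
                m.compound_id for m in screen_flexible(hyp, actives)
            }
            assert len(matched) / len(actives) >= frac


class TestValidateAndSelect:
    def test_perfect_hypothesis_selected(self):
        hyp = fx.make_random_hypothesis("AAR", seed=1)
        act_poses, _ = fx.make_planted_pose_set(hyp, 10, 0, seed=2)
        dec_poses, _ = fx.make_planted_pose_set(hyp, 0, 10, seed=3)
        best, metrics = validate_and_select([hyp], act_poses, dec_poses)
        assert best is hyp
        m = metrics[hyp.id]
        assert m.sensitivity == m.specificity == 1.0

    def test_sensitivity_wins_over_specificity(self):
        # two hypotheses screened on the same planted set: the one keeping
        # more actives is selected even if it lets more decoys through
        base = fx.make_random_hypothesis("AAR", seed=4)
        act_poses, _ = fx.make_planted_pose_set(base, 9, 0, seed=5)
        dec_poses, _ = fx.make_planted_pose_set(base, 0, 9, seed=6)
        loose = Hypothesis(
            "loose",
            [Site(s.kind, s.position.copy(), 30.0, s.required)
             for s in base.sites],
        )
        strict = Hypothesis(
            "strict",
            [Site(s.kind, s.position.copy(), 0.05, s.required)
             for s in base.sites],
        )
        best, metrics = validate_and_select(
            [strict, loose], act_poses, dec_poses
        )
        assert metrics["loose"].sensitivity > metrics["strict"].sensitivity
        assert best.id == "loose"

    def test_single_hypothesis_returned(self):
        hyp = fx.make_random_hypothesis("AD", seed=8)
        act, _ = fx.make_planted_pose_set(hyp, 3, 0, seed=8)
        dec, _ = fx.make_planted_pose_set(hyp, 0, 3, seed=9)
        best, _ = validate_and_select([hyp], act, dec)
        assert best is hyp

    def test_empty_validation_set_rejected(self):
        hyp = fx.make_random_hypothesis("AD", seed=8)
        with pytest.raises(ValueError):
            validate_and_select([hyp], [], [])
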