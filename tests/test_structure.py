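"""Structural metrics: anchor distance, contacts, H-bonds, MM/GBSA window."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from neoprior.structure import (
    EnergySeries,
    anchor_distance,
    count_contacts,
    count_hbonds,
    detect_peptide_chain,
    mmgbsa_window,
    read_structure,
)
from neoprior.synthetic import simulate_energy_series, simulate_structure

from conftest import build_frame


def peptide_ca_frame(coords):
    """CA-only peptide chain P with the given per-residue coordinates."""
    return build_frame(
        [("P", i + 1, "CA", "C", *xyz) for i, xyz in enumerate(coords)]
    )


def nine_residue_frame(p2, p9):
    coords = [(float(i), 100.0, 100.0) for i in range(9)]
    coords[1], coords[8] = p2, p9
    return peptide_ca_frame(coords)


class TestAnchorDistance:
    @pytest.mark.parametrize(
        "p2,p9,expected",
        [
            ((0, 0, 0), (16, 0, 0), 16.0),
            ((5, 5, 5), (5, 5, 5), 0.0),
            ((0, 0, 0), (3, 4, 0), 5.0),
        ],
    )
    def test_closed_form_distances(self, p2, p9, expected):
        frame = nine_residue_frame(p2, p9)
        assert anchor_distance(frame, "P") == pytest.approx(expected)

    def test_missing_ca_named_in_error(self):
        records = [("P", i + 1, "CA", "C", float(i), 0, 0) for i in range(9)]
        records[8] = ("P", 9, "CB", "C", 8.0, 0, 0)
        with pytest.raises(ValueError, match="P9"):
            anchor_distance(build_frame(records), "P")

    def test_peptide_chain_auto_detected(self):
        atoms = simulate_structure(n_peptide_res=9, seed=0)
        assert detect_peptide_chain(atoms) == "P"
        assert anchor_distance(atoms) == anchor_distance(atoms, "P")

    def test_extended_nine_mer_spans_over_16_angstroms(self):
        # 3.8 A Calpha spacing: P2-P9 = 7 * 3.8 = 26.6 A
        atoms = simulate_structure(n_peptide_res=9, seed=1)
        assert anchor_distance(atoms, "P") == pytest.approx(26.6, abs=1e-3)


def random_two_chain_frame(rng, n_per_chain=50):
    records = []
    for chain in ("P", "A"):
        for i in range(n_per_chain):
            element = rng.choice(["C", "N", "O", "H"], p=[0.5, 0.2, 0.2, 0.1])
            name = "CA" if element == "C" else element
            records.append(
                (chain, i + 1, name, element, *rng.uniform(0, 15, size=3))
            )
    return build_frame(records)


class TestCountContacts:
    def test_single_pair_inside_and_outside_cutoff(self):
        frame = build_frame(
            [("P", 1, "CA", "C", 0, 0, 0), ("A", 1, "CA", "C", 4.0, 0, 0)]
        )
        assert count_contacts(frame, "P", "A", cutoff=4.5) == 1
        assert count_contacts(frame, "P", "A", cutoff=3.5) == 0

    def test_hydrogens_excluded_by_default(self):
        frame = build_frame(
            [("P", 1, "H", "H", 0, 0, 0), ("A", 1, "CA", "C", 1.0, 0, 0)]
        )
        assert count_contacts(frame, "P", "A") == 0
        assert count_contacts(frame, "P", "A", heavy_only=False) == 1

    def test_unknown_chain_rejected(self):
        frame = build_frame([("P", 1, "CA", "C", 0, 0, 0)])
        with pytest.raises(ValueError, match="'B'"):
            count_contacts(frame, "P", "B")

    def test_matches_all_pairs_oracle_on_random_frames(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            frame = random_two_chain_frame(rng)
            for cutoff in (3.0, 4.5, 6.0):
                p = frame[(frame.chain_id == "P") & (frame.element != "H")]
                a = frame[(frame.chain_id == "A") & (frame.element != "H")]
                brute = sum(
                    np.linalg.norm(x - y) <= cutoff
                    for x in p.coord
                    for y in a.coord
                )
                assert count_contacts(frame, "P", "A", cutoff=cutoff) == brute

    def test_monotone_in_cutoff_and_rigid_motion_invariant(self):
        rng = np.random.default_rng(11)
        frame = random_two_chain_frame(rng)
        counts = [count_contacts(frame, "P", "A", c) for c in (2.0, 4.0, 6.0, 8.0)]
        assert counts == sorted(counts)
        rot = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        moved = frame.copy()
        moved.coord = frame.coord @ rot.T + np.array([10.0, -3.0, 2.5])
        assert count_contacts(moved, "P", "A") == count_contacts(frame, "P", "A")
        assert anchor_distance(moved, "P", 1, 2) == pytest.approx(
            anchor_distance(frame, "P", 1, 2)
        )


def hbond_frame(d_a_dist, angle_deg):
    """Donor N-H on chain P, acceptor O on chain A at a set geometry.

    H sits 1.0 A from the donor along +x; the acceptor is placed so the
    D-H...A angle at H equals ``angle_deg`` with |D-A| = ``d_a_dist``.
    """
    d = np.array([0.0, 0.0, 0.0])
    h = np.array([1.0, 0.0, 0.0])
    theta = np.deg2rad(180.0 - angle_deg)  # deviation from linearity
    # position A at the requested D-A distance subject to the angle at H
    direction = np.array([np.cos(theta), np.sin(theta), 0.0])
    lo, hi = 0.0, 10.0
    for _ in range(80):  # bisect on the H-A length to hit |D-A|
        mid = (lo + hi) / 2
        a = h + mid * direction
        if np.linalg.norm(a - d) < d_a_dist:
            lo = mid
        else:
            hi = mid
    a = h + ((lo + hi) / 2) * direction
    return build_frame(
        [
            ("P", 1, "N", "N", *d),
            ("P", 1, "H", "H", *h),
            ("A", 1, "O", "O", *a),
        ]
    )


class TestCountHbonds:
    def test_linear_short_bond_counts(self):
        assert count_hbonds(hbond_frame(2.9, 180.0), "P", "A") == 1

    def test_long_distance_never_counts(self):
        assert count_hbonds(hbond_frame(4.0, 180.0), "P", "A") == 0

    def test_bent_geometry_rejected(self):
        assert count_hbonds(hbond_frame(2.9, 90.0), "P", "A") == 0

    def test_angle_cutoff_boundary(self):
        assert count_hbonds(hbond_frame(2.9, 125.0), "P", "A") == 1
        assert count_hbonds(hbond_frame(2.9, 115.0), "P", "A") == 0

    def test_no_hydrogens_raises_and_fallback_works(self):
        frame = build_frame(
            [("P", 1, "N", "N", 0, 0, 0), ("A", 1, "O", "O", 2.9, 0, 0)]
        )
        with pytest.raises(ValueError, match="distance_only"):
            count_hbonds(frame, "P", "A")
        assert count_hbonds(frame, "P", "A", distance_only=True) == 1

    def test_matches_brute_force_oracle_on_random_frames(self):
        rng = np.random.default_rng(23)
        for _ in range(5):
            frame = random_two_chain_frame(rng)
            got = count_hbonds(frame, "P", "A")
            assert got == brute_force_hbonds(frame, "P", "A")


def brute_force_hbonds(frame, donor_chain, acceptor_chain, d_cut=3.5, ang_cut=120.0):
    donors = frame[
        (frame.chain_id == donor_chain) & np.isin(frame.element, ("N", "O"))
    ]
    hydrogens = frame[(frame.chain_id == donor_chain) & (frame.element == "H")]
    acceptors = frame[
        (frame.chain_id == acceptor_chain) & np.isin(frame.element, ("N", "O"))
    ]
    n = 0
    for d in donors.coord:
        hs = [h for h in hydrogens.coord if np.linalg.norm(h - d) <= 1.3]
        for a in acceptors.coord:
            if np.linalg.norm(a - d) > d_cut:
                continue
            for h in hs:
                v1, v2 = d - h, a - h
                cos = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                if np.degrees(np.arccos(np.clip(cos, -1, 1))) >= ang_cut:
                    n += 1
                    break
    return n


class TestMmgbsaWindow:
    def test_constant_components(self):
        series = EnergySeries(
            time_ns=np.linspace(0, 100, 11),
            g_complex=np.full(11, -100.0),
            g_receptor=np.full(11, -40.0),
            g_ligand=np.full(11, -30.0),
        )
        stats = mmgbsa_window(series)
        assert (stats.mean, stats.sd) == (-30.0, 0.0)
        assert stats.n_frames == 3  # t = 80, 90, 100

    def test_frames_before_window_do_not_matter(self):
        base = simulate_energy_series(200, mean_dg=-30.0, noise_sd=0.0, seed=0)
        altered = EnergySeries(
            time_ns=base.time_ns,
            g_complex=np.where(base.time_ns < 80, 999.0, base.g_complex),
            g_receptor=base.g_receptor,
            g_ligand=base.g_ligand,
        )
        assert mmgbsa_window(altered) == mmgbsa_window(base)

    def test_window_mean_within_clt_bound_of_planted_value(self):
        series = simulate_energy_series(2000, mean_dg=-30.0, noise_sd=1.0, seed=1)
        stats = mmgbsa_window(series)
        assert stats.n_frames == 400
        assert abs(stats.mean + 30.0) <= 3.0 / np.sqrt(stats.n_frames)

    def test_empty_window_rejected(self):
        series = simulate_energy_series(10, seed=0, total_ns=50.0)
        with pytest.raises(ValueError, match="window"):
            mmgbsa_window(series, (80.0, 100.0))

    def test_times_must_increase(self):
        with pytest.raises(ValueError):
            EnergySeries(
                time_ns=np.array([0.0, 0.0]),
                g_complex=np.zeros(2),
                g_receptor=np.zeros(2),
                g_ligand=np.zeros(2),
            )


class TestIO:
    def test_energy_series_tsv_round_trip(self, tmp_path):
        series = simulate_energy_series(50, mean_dg=-12.5, noise_sd=0.2, seed=4)
        path = tmp_path / "energy.tsv"
        series.to_tsv(str(path))
        back = EnergySeries.from_tsv(str(path))
        np.testing.assert_allclose(back.dg, series.dg)

    def test_pdb_round_trip_preserves_metrics(self, tmp_path):
        from biotite.structure.io.pdb import PDBFile

        atoms = simulate_structure(seed=5)
        path = tmp_path / "complex.pdb"
        pdb = PDBFile()
        pdb.set_structure(atoms)
        pdb.write(str(path))
        back = read_structure(str(path))
        assert anchor_distance(back, "P") == pytest.approx(
            anchor_distance(atoms, "P"), abs=1e-2
        )
        assert count_contacts(back, "P", "A") == count_contacts(atoms, "P", "A")
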