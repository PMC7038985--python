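"""H-bond detection/classification and the LJ stacking partition."""

import numpy as np
import pytest

from dnastretch import (
    FrameAnalyzer,
    HBondCriteria,
    LJTable,
    build_duplex,
    detect_hbonds,
    stacking_energies,
)
from dnastretch.templates import (
    ACCEPTORS,
    DONOR_HYDROGENS,
    PURINES,
    WC_HBOND_ATOMS,
)


# -- independent brute-force oracles ------------------------------------------

def brute_force_hbonds(duplex, coords, criteria=HBondCriteria()):
    """Exhaustive scan over all donor/H/acceptor triples (loop-based oracle)."""
    atoms = []  # (strand, res_index, base, name, role, xyz)
    k = 0
    for nt in duplex.nucleotides:
        for a in nt.atoms:
            atoms.append((nt.strand, nt.index, nt.base, a.name, a.role, coords[k]))
            k += 1
    found = []
    for sd, rd, bd, nd, roled, pd in atoms:
        if roled != "base-donor":
            continue
        for hname in DONOR_HYDROGENS[(bd, nd)]:
            ph = next(p for s, r, b, n, _, p in atoms
                      if s == sd and r == rd and n == hname)
            for sa, ra, ba, na, rolea, pa in atoms:
                if rolea != "base-acceptor" or (sa, ra) == (sd, rd):
                    continue
                dist = float(np.linalg.norm(pa - pd))
                v1, v2 = pd - ph, pa - ph
                ang = float(np.rad2deg(np.arccos(
                    np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))))
                if dist <= criteria.max_distance and ang >= criteria.min_angle:
                    # canonical: WC atom pair between WC partners
                    n_bp = duplex.n_bp
                    bp_d = rd if sd == 1 else n_bp + 1 - rd
                    bp_a = ra if sa == 1 else n_bp + 1 - ra
                    if bd in PURINES:
                        wc = (nd, na) in WC_HBOND_ATOMS.get((bd, ba), ())
                    else:
                        wc = (na, nd) in WC_HBOND_ATOMS.get((ba, bd), ())
                    cls = ("canonical" if (bp_d == bp_a and sd != sa and wc)
                           else "non-canonical")
                    found.append((f"{sd}:{rd}:{nd}", f"{sd}:{rd}:{hname}",
                                  f"{sa}:{ra}:{na}", cls, bp_d))
    return sorted(found)


def naive_lj_residue_pairs(duplex, coords, lj=LJTable()):
    """Per-residue-pair LJ sums by an explicit double loop."""
    import math

    atoms = []
    k = 0
    for nt in duplex.nucleotides:
        for a in nt.atoms:
            atoms.append(((nt.strand, nt.index), a.element, coords[k]))
            k += 1
    energies = {}
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            (ri, ei, pi), (rj, ej, pj) = atoms[i], atoms[j]
            if ri == rj:
                continue
            r = math.dist(pi, pj)
            eps = math.sqrt(lj.epsilon[ei] * lj.epsilon[ej])
            rmin = lj.rmin_half[ei] + lj.rmin_half[ej]
            sr6 = (rmin / r) ** 6
            e = eps * (sr6 * sr6 - 2 * sr6)
            key = tuple(sorted((ri, rj)))
            energies[key] = energies.get(key, 0.0) + e
    return energies


# -- detection ----------------------------------------------------------------

class TestDetectHBonds:
    def test_central_gc_pair_has_three_bonds(self, cg24, cg24_analyzer):
        bonds = cg24_analyzer.detect_hbonds(cg24.coordinates())
        per_bp = {}
        for b in bonds:
            per_bp.setdefault(b.bp_assignment, []).append(b)
        assert len(per_bp[12]) == 3
        assert all(b.hbond_class == "canonical" for b in per_bp[12])

    def test_every_ideal_pair_count(self):
        for seq, expected in [("AT" * 12, 2), ("A" * 24, 2),
                              ("CG" * 12, 3), ("C" * 24, 3)]:
            d = build_duplex(seq)
            ana = FrameAnalyzer(d)
            canon, noncanon = ana.classify_hbonds(
                ana.detect_hbonds(d.coordinates()))
            assert np.all(canon == expected), seq
            assert np.all(noncanon == 0), seq

    def test_distance_boundary_exclusive_beyond(self):
        # a straight N-H...O geometry at 3.6 A donor-acceptor fails; at
        # exactly 3.5 A with angle >= 120 it is reported (inclusive bounds)
        d = build_duplex("AT")
        ana = FrameAnalyzer(d)
        coords = d.coordinates()
        table = d.atom_table()
        don = table[(table["name"] == "N6")].index[0]
        hyd = table[(table["name"] == "H61")].index[0]
        acc = table[(table["residue_index"] == 2) & (table["strand"] == 2)
                    & (table["name"] == "O4")].index[0]
        # axis-aligned collinear N-H...O geometry so distances are exactly
        # representable: donor at origin offset, H at +1 x, acceptor at +d x
        far = coords.copy()
        far[hyd] = far[don] + [1.0, 0.0, 0.0]
        far[acc] = far[don] + [3.6, 0.0, 0.0]
        labels = {(b.donor, b.acceptor) for b in ana.detect_hbonds(far)}
        assert ("1:1:N6", "2:2:O4") not in labels
        edge = coords.copy()
        edge[hyd] = edge[don] + [1.0, 0.0, 0.0]
        edge[acc] = edge[don] + [3.5, 0.0, 0.0]
        labels = {(b.donor, b.acceptor) for b in ana.detect_hbonds(edge)}
        assert ("1:1:N6", "2:2:O4") in labels

    def test_angle_boundary_inclusive(self):
        d = build_duplex("AT")
        ana = FrameAnalyzer(d)
        coords = d.coordinates()
        table = d.atom_table()
        don = table[(table["name"] == "N6")].index[0]
        hyd = table[(table["name"] == "H61")].index[0]
        acc = table[(table["residue_index"] == 2) & (table["strand"] == 2)
                    & (table["name"] == "O4")].index[0]
        # acceptor placed for an exact 120.0 degree donor-H...acceptor angle
        u = coords[hyd] - coords[don]
        u /= np.linalg.norm(u)
        perp = np.cross(u, [0.0, 0.0, 1.0])
        perp /= np.linalg.norm(perp)
        direction = np.cos(np.deg2rad(60)) * u + np.sin(np.deg2rad(60)) * perp
        probe = coords.copy()
        probe[acc] = coords[hyd] + 2.0 * direction
        bonds = ana.detect_hbonds(probe)
        match = [b for b in bonds if b.acceptor == "2:2:O4" and b.donor == "1:1:N6"]
        assert match and match[0].angle == pytest.approx(120.0, abs=1e-9)

    def test_order_invariance_under_atom_shuffle(self, rng):
        d = build_duplex("ACG")
        ref = {(b.donor, b.hydrogen, b.acceptor)
               for b in detect_hbonds(d)}
        shuffled = d.with_coordinates(d.coordinates())
        for nt in shuffled.nucleotides:
            rng.shuffle(nt.atoms)
        got = {(b.donor, b.hydrogen, b.acceptor)
               for b in detect_hbonds(shuffled)}
        assert got == ref

    def test_brute_force_oracle_agreement(self, rng):
        # exhaustive triple scan on small duplexes, ideal and jittered
        for seq in ["AT", "GC", "ACGTAC"]:
            d = build_duplex(seq)
            ana = FrameAnalyzer(d)
            for jitter in (0.0, 0.3):
                coords = d.coordinates() + rng.normal(0, jitter,
                                                      d.coordinates().shape)
                got = sorted((b.donor, b.hydrogen, b.acceptor,
                              b.hbond_class, b.bp_assignment)
                             for b in ana.detect_hbonds(coords))
                assert got == brute_force_hbonds(d, coords), (seq, jitter)


class TestClassifyHBonds:
    def test_shifted_partner_bond_is_noncanonical(self):
        # force a contact between base 10 (strand 1) and the WC partner of
        # base 11: shift base 10 one helical step upward, landing it in WC
        # register with residue 2:14 (which is not its own partner, 2:15)
        d = build_duplex("A" * 24)
        ana = FrameAnalyzer(d)
        coords = d.coordinates()
        table = d.atom_table()
        sel = ((table["strand"] == 1) & (table["residue_index"] == 10)
               & table["role"].str.startswith("base")).to_numpy()
        a = np.deg2rad(36.0)
        R = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0],
                      [0, 0, 1.0]])
        coords[sel] = coords[sel] @ R.T
        coords[sel, 2] += 3.3
        bonds = ana.detect_hbonds(coords)
        cross = [b for b in bonds
                 if b.donor.startswith("1:10:") and b.acceptor.startswith("2:14:")]
        assert cross
        assert all(b.hbond_class == "non-canonical" for b in cross)

    def test_counts_assigned_to_donor_bp(self, cg24, cg24_analyzer):
        canon, noncanon = cg24_analyzer.classify_hbonds(
            cg24_analyzer.detect_hbonds(cg24.coordinates()))
        assert canon.sum() == 3 * 24
        assert noncanon.sum() == 0


# -- stacking -----------------------------------------------------------------

class TestStacking:
    def test_lj_minimum_is_minus_epsilon(self):
        lj = LJTable()
        eps, rmin = lj.pair_params("C", "O")
        assert lj.pair_energy("C", "O", rmin) == pytest.approx(-eps, abs=1e-12)
        assert eps == pytest.approx(np.sqrt(0.086 * 0.21))
        assert rmin == pytest.approx(1.908 + 1.661)

    def test_unknown_element_rejected(self):
        lj = LJTable()
        with pytest.raises(KeyError, match="Xx"):
            lj.pair_params("Xx", "C")

    def test_naive_double_loop_oracle(self, rng):
        # <=200-atom frames: 3 bp = 156 atoms; ideal and jittered geometry
        d = build_duplex("ACG")
        ana = FrameAnalyzer(d)
        for jitter in (0.0, 0.2):
            coords = d.coordinates() + rng.normal(0, jitter, d.coordinates().shape)
            assert coords.shape[0] <= 200
            oracle = naive_lj_residue_pairs(d, coords)
            e_res = ana.residue_pair_energies(coords)
            res_ids = ana._res_ids
            for (ra, rb), e in oracle.items():
                ia, ib = res_ids.index(ra), res_ids.index(rb)
                assert e_res[ia, ib] == pytest.approx(e, abs=1e-10)

    def test_channel_partition_covers_all_pairs(self, at24_analyzer):
        ana = at24_analyzer
        n_res = len(ana._res_ids)
        canon = ana._canon_mask
        noncanon = ana._noncanon_mask
        partner = np.zeros_like(canon)
        for a, b in ana._partner.items():
            partner[a, b] = True
        eye = np.eye(n_res, dtype=bool)
        total = canon.astype(int) + noncanon.astype(int) + partner.astype(int) \
            + eye.astype(int)
        assert np.all(total == 1)
        assert not np.any(canon & noncanon)

    def test_interior_noncanonical_weaker_than_canonical(self, cg24):
        recs = stacking_energies(cg24)
        for r in recs:
            bp = r.index if r.strand == 1 else 25 - r.index
            if 3 <= bp <= 22:
                assert abs(r.noncanonical_energy) < abs(r.canonical_energy)

    def test_pair_energy_credited_to_both_participants(self, at24_analyzer):
        e_res = at24_analyzer.residue_pair_energies(
            at24_analyzer.duplex.coordinates())
        assert np.allclose(e_res, e_res.T, atol=1e-12)


class TestMonotoneDisruption:
    def test_severity_never_increases_canonical_counts(self):
        from dnastretch import (BubbleSpec, PerturbationSpec, StretchProtocol,
                                generate_trajectory)
        from dnastretch.metrics import analyze_trajectory

        d = build_duplex("AT" * 12)
        means = []
        for sev in (0.0, 0.05, 0.15, 0.5, 1.0):
            traj = generate_trajectory(
                d, StretchProtocol(n_steps=1, frames_per_window=50),
                PerturbationSpec(bubbles=(BubbleSpec(10, 13, 1, sev),),
                                 noise_sd=0.15),
                seed=11)
            m = analyze_trajectory(d, traj)
            means.append(m.channel("canonical_hb")[9:13, 0].mean())
        assert all(a >= b - 1e-12 for a, b in zip(means, means[1:]))
        assert means[0] > 1.8
        assert means[-1] < 1.0
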