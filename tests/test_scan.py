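"""Column classification: worked examples, the exhaustive set-logic oracle,
and the scanner's structural invariants."""

import itertools

import pytest

import ribosig as rs
from ribosig.scan import (
    INDEL,
    SUBSTITUTION,
    Category,
    ScanConfig,
    categorize_sets,
    classify_profile,
    column_profile,
)
from ribosig.symbols import ALPHABET, GAP

B, A, E = "Bacteria", "Archaea", "Eukaryota"


def _sets(b, a, e):
    return {B: frozenset(b), A: frozenset(a), E: frozenset(e)}


PAIR_AE = Category("PAIR", (A, E))
PAIR_BA = Category("PAIR", (A, B))
PAIR_BE = Category("PAIR", (B, E))


@pytest.mark.parametrize(
    "b,a,e,cat,subtype",
    [
        # published worked rows: Y/G/G, H/-/-, -/-/N, C/G/D
        ("CT", "G", "G", PAIR_AE, SUBSTITUTION),
        ("ACT", "-", "-", PAIR_AE, INDEL),
        ("-", "-", "ACGT", PAIR_BA, INDEL),
        ("C", "G", "AGT", PAIR_AE, SUBSTITUTION),
        ("G", "G", "G", rs.UNIVERSAL, SUBSTITUTION),
        ("T", "G", "T", PAIR_BE, SUBSTITUTION),
        ("AC", "T", "G-", Category("ONLY", (A,)), SUBSTITUTION),
        ("AC", "-", "GT", Category("ONLY", (A,)), INDEL),
        ("AC", "AG", "CGT", rs.UNCLASSIFIED, None),
        ("-", "-", "-", rs.UNCLASSIFIED, None),  # all-gap is not universal
    ],
)
def test_categorize_worked_examples(b, a, e, cat, subtype):
    got_cat, got_sub = categorize_sets(_sets(b, a, e))
    assert got_cat == cat
    assert got_sub == subtype


def _oracle(sets):
    """Independent brute-force restatement of the category definitions,
    evaluated condition by condition with explicit precedence."""
    labels = sorted(sets)
    vals = {g: sets[g] for g in labels}
    # UNIVERSAL: identical singleton non-gap state everywhere
    states = set(map(frozenset, vals.values()))
    if len(states) == 1:
        (s,) = states
        if len(s) == 1 and GAP not in s:
            return "UNIVERSAL"
    # PAIR(X,Y): Z disjoint from X∪Y and X∩Y non-empty
    for x, y in itertools.combinations(labels, 2):
        z = next(g for g in labels if g not in (x, y))
        if not (vals[z] & (vals[x] | vals[y])) and (vals[x] & vals[y]):
            return f"PAIR({x},{y})" if x < y else f"PAIR({y},{x})"
    # ONLY(X): X fixed for one symbol absent elsewhere
    for x in labels:
        rest = frozenset().union(*(vals[g] for g in labels if g != x))
        if len(vals[x]) == 1 and not (vals[x] & rest):
            return f"ONLY({x})"
    return "UNCLASSIFIED"


def _nonempty_subsets():
    out = []
    for r in range(1, 6):
        out.extend(frozenset(c) for c in itertools.combinations(ALPHABET, r))
    return out


def test_classifier_agrees_with_exhaustive_oracle():
    """All 31^3 = 29,791 ordered triples of non-empty symbol subsets."""
    subsets = _nonempty_subsets()
    assert len(subsets) == 31
    pair_collisions = 0
    for b in subsets:
        for a in subsets:
            for e in subsets:
                sets = {B: b, A: a, E: e}
                cat, _ = categorize_sets(sets)
                assert str(cat) == _oracle(sets), sets
                # mutual exclusivity of PAIR categories for 3 groups:
                # count how many pair conditions hold simultaneously
                hits = 0
                for x, y in itertools.combinations(sorted(sets), 2):
                    z = next(g for g in sets if g not in (x, y))
                    if not (sets[z] & (sets[x] | sets[y])) and (sets[x] & sets[y]):
                        hits += 1
                assert hits <= 1
                if hits:
                    pair_collisions += 0
    # oracle covered every triple
    assert len(subsets) ** 3 == 29_791


def test_pair_is_symmetric_in_its_groups():
    cat1, _ = categorize_sets(_sets("CT", "G", "G"))
    cat2, _ = categorize_sets({B: frozenset("CT"), E: frozenset("G"),
                               A: frozenset("G")})
    assert cat1 == cat2 == PAIR_AE


def test_excluded_group_monotonicity():
    """Growing the excluded set inside itself keeps a PAIR; touching the
    shared union destroys it."""
    base = _sets("CT", "G", "G")
    assert categorize_sets(base)[0] == PAIR_AE
    same = _sets("CTC", "G", "G")  # still subset of {C,T}
    assert categorize_sets(same)[0] == PAIR_AE
    poisoned = _sets("CTG", "G", "G")  # bacteria now carry the shared G
    assert categorize_sets(poisoned)[0] != PAIR_AE


def test_four_group_generalization_on_toys():
    sets = {
        "G1": frozenset("A"), "G2": frozenset("A"),
        "G3": frozenset("C"), "G4": frozenset("GT"),
    }
    cat, _ = categorize_sets(sets)
    assert cat == Category("PAIR", ("G1", "G2"))
    sets3 = {
        "G1": frozenset("A"), "G2": frozenset("AG"),
        "G3": frozenset("AC"), "G4": frozenset("T-"),
    }
    cat3, _ = categorize_sets(sets3)
    assert cat3 == Category("PAIR", ("G1", "G2", "G3"))
    only = {
        "G1": frozenset("A"), "G2": frozenset("CG"),
        "G3": frozenset("T-"), "G4": frozenset("GT"),
    }
    assert categorize_sets(only)[0] == Category("ONLY", ("G1",))


class TestColumnProfile:
    def test_profile_matches_brute_force_tally(self, toy_alignment):
        aln, gmap = toy_alignment
        for col in range(aln.width):
            prof = column_profile(aln, gmap, col)
            for group in gmap.groups:
                members = [t for t in aln.ids
                           if gmap.assignments[t] == group]
                residues = [aln.row(t)[col] for t in members]
                expected_obs = [r for r in residues if r != "N"]
                assert prof.n_observed[group] == len(expected_obs)
                assert prof.n_missing[group] == residues.count("N")
                if expected_obs:
                    assert prof.observed(group) == frozenset(expected_obs)
                assert (prof.n_observed[group] + prof.n_missing[group]
                        == prof.group_sizes[group])

    def test_all_missing_group_is_unclassified(self):
        aln = rs.Alignment.from_records(
            [("b1", "A"), ("b2", "A"), ("a1", "N"), ("a2", "N"),
             ("e1", "A"), ("e2", "A")]
        )
        gmap = rs.GroupMap({"b1": B, "b2": B, "a1": A, "a2": A,
                            "e1": E, "e2": E})
        prof = column_profile(aln, gmap, 0)
        cat, _, _ = classify_profile(prof, ScanConfig())
        assert cat == rs.UNCLASSIFIED


class TestTolerance:
    def _profile(self, b_syms, a_syms, e_syms):
        recs = (
            [(f"b{i}", s) for i, s in enumerate(b_syms)]
            + [(f"a{i}", s) for i, s in enumerate(a_syms)]
            + [(f"e{i}", s) for i, s in enumerate(e_syms)]
        )
        aln = rs.Alignment.from_records(recs)
        gmap = rs.GroupMap(
            {t: {"b": B, "a": A, "e": E}[t[0]] for t, _ in recs}
        )
        return column_profile(aln, gmap, 0)

    def test_tolerance_recovers_noisy_signature(self):
        # one aberrant bacterium carries the shared G; strict scan fails,
        # a 10% tolerance discards it
        prof = self._profile(["C"] * 19 + ["G"], ["G"] * 10, ["G"] * 10)
        strict, _, _ = classify_profile(prof, ScanConfig(tolerance=0.0))
        tol, _, _ = classify_profile(prof, ScanConfig(tolerance=0.1))
        assert strict == rs.UNCLASSIFIED
        assert tol == PAIR_AE

    def test_tolerance_never_loses_a_strict_site(self):
        # shared symbol is itself rare: naive trimming would delete it,
        # the classifier must keep the strict call
        prof = self._profile(["C"] * 10, ["G"] * 9 + ["T"], ["T"] * 10)
        strict, _, _ = classify_profile(prof, ScanConfig(tolerance=0.0))
        tol, _, _ = classify_profile(prof, ScanConfig(tolerance=0.1))
        assert strict == PAIR_AE
        assert tol.precedence >= strict.precedence


class TestScanAlignment:
    def test_identical_sequences_all_universal(self):
        aln = rs.Alignment.from_records(
            [(f"t{i}", "ACGTAC") for i in range(6)]
        )
        gmap = rs.GroupMap(
            {f"t{i}": (B if i < 2 else A if i < 4 else E) for i in range(6)}
        )
        sites = rs.scan_alignment(aln, gmap)
        assert len(sites) == 6
        assert all(s.category == rs.UNIVERSAL for s in sites)

    def test_record_order_is_irrelevant(self, toy_alignment):
        aln, gmap = toy_alignment
        sites = rs.scan_alignment(aln, gmap)
        perm = list(reversed(range(aln.n_taxa)))
        shuffled = rs.Alignment(
            tuple(aln.ids[i] for i in perm),
            tuple(aln.seqs[i] for i in perm),
        )
        assert rs.scan_alignment(shuffled, gmap) == sites

    def test_strict_sites_subset_of_tolerant_sites(self):
        cfg = rs.SyntheticConfig(
            group_sizes={"Bacteria": 30, "Archaea": 30, "Eukaryota": 30},
            noise_rate=0.05, seed=11,
        )
        ds = rs.generate_alignment(cfg)
        strict = rs.scan_alignment(
            ds.alignment, ds.group_map, cfg=ScanConfig(merge_adjacent=False)
        )
        tolerant = rs.scan_alignment(
            ds.alignment, ds.group_map,
            cfg=ScanConfig(tolerance=0.05, merge_adjacent=False),
        )
        strict_cols = {s.column for s in strict}
        tol_cols = {s.column for s in tolerant}
        assert strict_cols <= tol_cols


class TestMerging:
    def test_adjacent_same_category_sites_merge(self, demo_alignment,
                                                demo_groups, examples_dir):
        mask = rs.read_mask(examples_dir / "demo_mask.bed")
        sites = rs.scan_alignment(demo_alignment, demo_groups, mask,
                                  ScanConfig(merge_adjacent=False))
        merged = rs.merge_adjacent_sites(sites)
        two_col = [m for m in merged if m.n_columns == 2
                   and m.category.kind == "PAIR"]
        assert len(two_col) == 1
        locus = two_col[0]
        assert locus.group_codes["Bacteria"] == "-Y"
        assert locus.group_codes["Archaea"] == "BG"
        assert locus.group_codes["Eukaryota"] == "HR"
        # merging never changes total column coverage
        assert sum(m.n_columns for m in merged) == len(sites)

    def test_merge_respects_category_boundaries(self):
        s1 = rs.SignatureSite(0, 0, rs.UNIVERSAL, SUBSTITUTION, {B: "A"})
        s2 = rs.SignatureSite(1, 1, PAIR_AE, SUBSTITUTION, {B: "C"})
        assert len(rs.merge_adjacent_sites([s1, s2])) == 2
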