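"""Alignment statistics against an independent Gotoh DP oracle, and
ortholog clustering against brute-force component search."""

import itertools
import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from femscreen.homology import (
    AMINO_ACIDS, GAP_EXTEND, GAP_OPEN, HomologyError, OrthologGroup,
    ProteinRecord, align, bit_score, cluster_orthologs, core_genome, evalue,
    search_hits,
)

B62 = substitution_matrices.load("BLOSUM62")
NEG = -1e12


def gotoh_score(a: str, b: str, mode: str) -> float:
    """Independent affine-gap DP (three-state Gotoh recursion); end gaps
    penalized in global mode, zero floor on alignment starts in local mode."""
    m, n = len(a), len(b)
    M = np.full((m + 1, n + 1), NEG)
    X = np.full((m + 1, n + 1), NEG)
    Y = np.full((m + 1, n + 1), NEG)
    local = mode == "local"
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        X[i, 0] = NEG if local else GAP_OPEN + (i - 1) * GAP_EXTEND
        if local:
            M[i, 0] = 0.0
    for j in range(1, n + 1):
        Y[0, j] = NEG if local else GAP_OPEN + (j - 1) * GAP_EXTEND
        if local:
            M[0, j] = 0.0
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = B62[a[i - 1], b[j - 1]]
            M[i, j] = s + max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            if local:
                M[i, j] = max(M[i, j], 0.0)
                best = max(best, M[i, j])
            X[i, j] = max(M[i - 1, j] + GAP_OPEN, X[i - 1, j] + GAP_EXTEND,
                          Y[i - 1, j] + GAP_OPEN)
            Y[i, j] = max(M[i, j - 1] + GAP_OPEN, Y[i, j - 1] + GAP_EXTEND,
                          X[i, j - 1] + GAP_OPEN)
    return best if local else float(max(M[m, n], X[m, n], Y[m, n]))


def _random_pair(rng, related: bool) -> tuple[str, str]:
    aa = list(AMINO_ACIDS)
    la, lb = rng.integers(5, 21, 2)
    a = "".join(rng.choice(aa, la))
    if not related:
        return a, "".join(rng.choice(aa, lb))
    b = list(a)
    for pos in rng.choice(la, max(1, la // 5), replace=False):
        b[pos] = aa[int(rng.integers(20))]
    return a, "".join(b)


@pytest.mark.parametrize("mode", ["global", "local"])
def test_alignment_scores_match_bruteforce_dp(mode):
    rng = np.random.default_rng(7)
    for trial in range(40):
        a, b = _random_pair(rng, related=trial % 3 == 0)
        hit = align(ProteinRecord("x", "q", a), ProteinRecord("y", "s", b), mode)
        assert hit.raw_score == pytest.approx(gotoh_score(a, b, mode), abs=1e-9)


def test_global_identity_of_substituted_pair():
    # 43-mer with 2 substitutions, ungapped: identity 41/43 = 95.35%
    rng = np.random.default_rng(1)
    a = "".join(rng.choice(list(AMINO_ACIDS), 43))
    b = list(a)
    b[10] = "W" if a[10] != "W" else "Y"
    b[30] = "W" if a[30] != "W" else "Y"
    hit = align(ProteinRecord("x", "q", a), ProteinRecord("y", "s", "".join(b)),
                "global")
    assert hit.identity == pytest.approx(41 / 43)
    assert round(100 * hit.identity, 2) == 95.35
    assert hit.query_coverage == 1.0


def test_identical_sequences_align_perfectly():
    seq = "MKVLATTHQWERPLSDFGHKLCVNMAT"
    hit = align(ProteinRecord("x", "a", seq), ProteinRecord("y", "b", seq), "global")
    assert hit.identity == 1.0 and hit.query_coverage == 1.0


def test_global_identity_is_symmetric():
    rng = np.random.default_rng(3)
    for trial in range(10):
        a, b = _random_pair(rng, related=True)
        ab = align(ProteinRecord("x", "q", a), ProteinRecord("y", "s", b), "global")
        ba = align(ProteinRecord("y", "s", b), ProteinRecord("x", "q", a), "global")
        assert ab.identity == pytest.approx(ba.identity)


def test_invalid_sequences_rejected():
    with pytest.raises(HomologyError):
        ProteinRecord("x", "empty", "")
    with pytest.raises(HomologyError):
        ProteinRecord("x", "bad", "MKV1")


def test_evalue_arithmetic():
    assert evalue(20.0, 100, 1000) == pytest.approx(1e5 * 2.0 ** -20)
    assert evalue(0.0, 1, 1) == 1.0
    assert evalue(1000.0, 100, 100) < 1e-250  # vanishes for huge scores
    # bit score definition round-trips through the Karlin-Altschul constants
    assert bit_score(0.0) == pytest.approx(-math.log(0.041) / math.log(2))


def _pairwise_hits(records, identity_matrix):
    """Synthetic hit table with prescribed identities and tiny e-values."""
    from femscreen.homology import HomologyHit

    hits = []
    for (i, a), (j, b) in itertools.permutations(enumerate(records), 2):
        hits.append(
            HomologyHit(query=a.key, subject=b.key,
                        identity=identity_matrix[i][j], query_coverage=1.0,
                        bit_score=200.0, evalue=1e-30)
        )
    return hits


def _brute_force_components(keys, edges):
    groups = []
    remaining = set(keys)
    while remaining:
        node = remaining.pop()
        component = {node}
        frontier = [node]
        while frontier:
            current = frontier.pop()
            for x, y in edges:
                other = y if x == current else (x if y == current else None)
                if other is not None and other not in component:
                    component.add(other)
                    frontier.append(other)
        remaining -= component
        if len(component) >= 2:
            groups.append(frozenset(component))
    return set(groups)


def test_clustering_matches_bruteforce_components():
    # two families at 95% within, 40% between -> two groups
    records = [ProteinRecord(f"g{i}", f"gene{i}", "M" * 10) for i in range(6)]
    identity = [[0.0] * 6 for _ in range(6)]
    for i, j in itertools.combinations(range(6), 2):
        same_family = (i < 3) == (j < 3)
        identity[i][j] = identity[j][i] = 0.95 if same_family else 0.40
    hits = _pairwise_hits(records, identity)
    groups = cluster_orthologs(hits, min_identity=0.70, max_evalue=1e-6)
    expected_edges = [
        (records[i].key, records[j].key)
        for i, j in itertools.combinations(range(6), 2)
        if identity[i][j] >= 0.70
    ]
    expected = _brute_force_components([r.key for r in records], expected_edges)
    assert {g.members for g in groups} == expected
    assert len(groups) == 2


def test_clustering_all_below_threshold_gives_no_groups():
    records = [ProteinRecord(f"g{i}", f"gene{i}", "M" * 10) for i in range(4)]
    identity = [[0.60] * 4 for _ in range(4)]
    assert cluster_orthologs(_pairwise_hits(records, identity)) == []


def test_clustering_invariant_under_row_order():
    rng = np.random.default_rng(11)
    records = [ProteinRecord(f"g{i}", f"gene{i}", "M" * 10) for i in range(8)]
    identity = [[0.0] * 8 for _ in range(8)]
    for i, j in itertools.combinations(range(8), 2):
        identity[i][j] = identity[j][i] = float(rng.choice([0.5, 0.75, 0.95]))
    hits = _pairwise_hits(records, identity)
    reference = cluster_orthologs(hits)
    for _ in range(3):
        shuffled = [hits[k] for k in rng.permutation(len(hits))]
        assert cluster_orthologs(shuffled) == reference


def test_core_genome_requires_every_genome():
    g_all = OrthologGroup("OG1", frozenset({("a", "1"), ("b", "2"), ("c", "3")}))
    g_partial = OrthologGroup("OG2", frozenset({("a", "4"), ("b", "5")}))
    assert core_genome([g_all, g_partial], ["a", "b", "c"]) == [g_all]
    with pytest.raises(HomologyError):
        core_genome([g_all], [])


def test_planted_families_recovered_from_sequence_search():
    """End-to-end: mutated protein families cluster into exactly the planted
    groups; unrelated proteins stay unclustered."""
    from femscreen.synthetic_data import _mutate_spread, random_protein

    rng = np.random.default_rng(23)
    records = []
    planted = []
    for fam in range(4):
        parent = random_protein(rng, 80)
        family = []
        for genome in ("A", "B", "C"):
            seq = parent if genome == "A" else _mutate_spread(parent, 12, rng)
            rec = ProteinRecord(genome, f"f{fam}_{genome}", seq)
            records.append(rec)
            family.append(rec.key)
        planted.append(frozenset(family))
    for i in range(5):  # unrelated background
        records.append(ProteinRecord("A", f"bg{i}", random_protein(rng, 80)))
    groups = cluster_orthologs(search_hits(records))
    assert {g.members for g in groups} == set(planted)
    assert len(core_genome(groups, ["A", "B", "C"])) == 4
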