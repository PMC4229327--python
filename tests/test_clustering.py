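"""Identity definition, greedy clustering, chimera screening, universal merge."""

import numpy as np
import pytest
from conftest import mutate, random_dna, records

from culturegap.clustering import (
    Cluster,
    IdentityParams,
    build_universal_otus,
    detect_chimeras,
    greedy_cluster,
    pairwise_identity,
)
from culturegap.io_formats import CULTURED_DATASET, SequenceRecord


def nw_affine_identity(a: str, b: str, denominator: str = "shorter_sequence"):
    """Independent oracle: exhaustive affine-gap global alignment by dynamic
    programming (match +1, mismatch -1, open -5, extend -1), maximizing the
    identity count among score-optimal alignments via traceback on scores."""
    n, m = len(a), len(b)
    NEG = -10**9
    # three-state affine DP over scores
    M = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    X = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in b
    Y = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in a
    M[0, 0] = 0
    for i in range(1, n + 1):
        X[i, 0] = -5 - (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = -5 - (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = 1 if a[i - 1] == b[j - 1] else -1
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - 5, X[i - 1, j] - 1, Y[i - 1, j] - 5)
            Y[i, j] = max(M[i, j - 1] - 5, Y[i, j - 1] - 1, X[i, j - 1] - 5)
    best = max(M[n, m], X[n, m], Y[n, m])
    # identity count: re-run DP tracking identities at equal score
    ids = {}
    for state, grid in (("M", M), ("X", X), ("Y", Y)):
        ids[state] = np.zeros((n + 1, m + 1), dtype=np.int64)
    ids["M"][0, 0] = 0
    for i in range(n + 1):
        for j in range(m + 1):
            if i == 0 and j == 0:
                continue
            if i > 0 and j > 0:
                s = 1 if a[i - 1] == b[j - 1] else -1
                opts = [(M[i - 1, j - 1], ids["M"][i - 1, j - 1]),
                        (X[i - 1, j - 1], ids["X"][i - 1, j - 1]),
                        (Y[i - 1, j - 1], ids["Y"][i - 1, j - 1])]
                sc = max(o[0] for o in opts)
                best_id = max(o[1] for o in opts if o[0] == sc)
                ids["M"][i, j] = best_id + (1 if s == 1 else 0)
            if i > 0:
                opts = [(M[i - 1, j] - 5, ids["M"][i - 1, j]),
                        (X[i - 1, j] - 1, ids["X"][i - 1, j]),
                        (Y[i - 1, j] - 5, ids["Y"][i - 1, j])]
                sc = max(o[0] for o in opts)
                ids["X"][i, j] = max(o[1] for o in opts if o[0] == sc)
            if j > 0:
                opts = [(M[i, j - 1] - 5, ids["M"][i, j - 1]),
                        (Y[i, j - 1] - 1, ids["Y"][i, j - 1]),
                        (X[i, j - 1] - 5, ids["X"][i, j - 1])]
                sc = max(o[0] for o in opts)
                ids["Y"][i, j] = max(o[1] for o in opts if o[0] == sc)
    finals = [(M[n, m], ids["M"][n, m]), (X[n, m], ids["X"][n, m]),
              (Y[n, m], ids["Y"][n, m])]
    identities = max(i for s, i in finals if s == best)
    denom = min(n, m) if denominator == "shorter_sequence" else None
    return best, identities, identities / denom if denom else None


class TestPairwiseIdentity:
    def test_identical_sequences_score_one(self, rng):
        s = random_dna(rng, 100)
        assert pairwise_identity(s, s) == 1.0

    def test_three_mismatches_over_100(self, rng):
        s = random_dna(rng, 100)
        t = mutate(s, 3, rng)
        assert pairwise_identity(s, t) == pytest.approx(0.97)

    def test_prefix_with_shorter_denominator_is_one(self, rng):
        s = random_dna(rng, 100)
        assert pairwise_identity(s, s[:50]) == pytest.approx(1.0)

    def test_symmetry(self, rng):
        a, b = random_dna(rng, 80), random_dna(rng, 70)
        assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))

    def test_agrees_with_exhaustive_dp_oracle(self, rng):
        for _ in range(6):
            n = int(rng.integers(20, 45))
            a = random_dna(rng, n)
            # mix of related and unrelated partners, some with indels
            b = mutate(a, int(rng.integers(0, 5)), rng)
            if rng.random() < 0.5:
                cut = int(rng.integers(1, 5))
                b = b[cut:]
            score, identities, oracle_identity = nw_affine_identity(a, b)
            got = pairwise_identity(a, b)
            denom = min(len(a), len(b))
            # same optimal score implies the same identity fraction here
            assert got == pytest.approx(identities / denom, abs=1.5 / denom)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")

    def test_alignment_length_denominator(self, rng):
        s = random_dna(rng, 100)
        params = IdentityParams(denominator_rule="alignment_length")
        assert pairwise_identity(s, s[:50], params) == pytest.approx(0.5)


def all_pairs_oracle(reads, threshold):
    """Independent oracle: connected components of the all-pairs identity
    graph at the threshold."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(r.id for r in reads)
    uniq = {}
    for r in reads:
        uniq.setdefault(r.residues, []).append(r.id)
    seqs = list(uniq)
    for i in range(len(seqs)):
        for ids in (uniq[seqs[i]],):
            for a, b in zip(ids, ids[1:]):
                g.add_edge(a, b)
        for j in range(i + 1, len(seqs)):
            if pairwise_identity(seqs[i], seqs[j]) >= threshold:
                g.add_edge(uniq[seqs[i]][0], uniq[seqs[j]][0])
    return {frozenset(c) for c in nx.connected_components(g)}


class TestGreedyCluster:
    def test_identical_reads_form_one_cluster(self, rng):
        s = random_dna(rng, 120)
        clusters = greedy_cluster(records([s] * 5))
        assert len(clusters) == 1
        assert clusters[0].size == 5

    def test_clearly_separated_groups_form_two_clusters(self, rng):
        a = random_dna(rng, 100)
        b = mutate(a, 10, rng)  # 90% cross-identity
        clusters = greedy_cluster(records([a, a, b, b]))
        assert len(clusters) == 2
        assert sorted(c.size for c in clusters) == [2, 2]

    def test_planted_groups_match_all_pairs_oracle(self, rng):
        # k groups at >=99% within / <=94% between; oracle = connected
        # components of the all-pairs identity graph
        k, n_reads = 8, 200
        centers = [random_dna(rng, 250) for _ in range(k)]
        reads = []
        for i in range(n_reads):
            g = int(rng.integers(0, k))
            seq = mutate(centers[g], int(rng.integers(0, 3)), rng)  # >=98.8%
            reads.append(SequenceRecord(id=f"r{i:04d}", dataset_id="d",
                                        residues=seq))
        clusters = greedy_cluster(reads)
        got = {frozenset(c.member_ids) for c in clusters}
        assert got == all_pairs_oracle(reads, 0.97)
        assert len(clusters) == k

    def test_partition_property(self, rng):
        reads = records([random_dna(rng, 60) for _ in range(30)])
        clusters = greedy_cluster(reads)
        seen = [rid for c in clusters for rid in c.member_ids]
        assert sorted(seen) == sorted(r.id for r in reads)

    def test_representative_separation(self, rng):
        centers = [random_dna(rng, 200) for _ in range(6)]
        reads = records([mutate(c, int(rng.integers(0, 4)), rng)
                         for c in centers for _ in range(5)])
        clusters = greedy_cluster(reads)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                assert pairwise_identity(
                    clusters[i].rep_seq, clusters[j].rep_seq
                ) < 0.97

    def test_invariant_to_input_order(self, rng):
        reads = records([mutate(random_dna(rng, 150), 1, rng)
                         for _ in range(20)])
        shuffled = list(reads)
        rng.shuffle(shuffled)
        a = greedy_cluster(reads)
        b = greedy_cluster(shuffled)
        assert {frozenset(c.member_ids) for c in a} == {
            frozenset(c.member_ids) for c in b
        }
        assert [c.rep_id for c in a] == [c.rep_id for c in b]

    def test_longest_first_with_lexicographic_ties(self, rng):
        s = random_dna(rng, 100)
        reads = [
            SequenceRecord(id="zz", dataset_id="d", residues=s),
            SequenceRecord(id="aa", dataset_id="d", residues=s),
            SequenceRecord(id="mm", dataset_id="d", residues=s + "ACGT"),
        ]
        clusters = greedy_cluster(reads)
        # the longest read founds the cluster and becomes representative
        assert clusters[0].rep_id == "mm"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            greedy_cluster([])


class TestDetectChimeras:
    def test_constructed_crossover_is_flagged(self, rng):
        a = random_dna(rng, 300)
        b = random_dna(rng, 300)  # ~25% identity to a: clearly divergent
        chim = a[:150] + b[150:]
        reads = [
            SequenceRecord(id="parentA", dataset_id="d", residues=a),
            SequenceRecord(id="parentB", dataset_id="d", residues=b),
            SequenceRecord(id="query", dataset_id="d", residues=chim),
        ]
        ab = {"parentA": 10, "parentB": 10, "query": 1}
        clean, chimeric = detect_chimeras(reads, ab)
        assert [r.id for r in chimeric] == ["query"]
        assert {r.id for r in clean} == {"parentA", "parentB"}

    def test_exact_copy_of_parent_is_clean(self, rng):
        a = random_dna(rng, 300)
        b = random_dna(rng, 300)
        reads = [
            SequenceRecord(id="parentA", dataset_id="d", residues=a),
            SequenceRecord(id="parentB", dataset_id="d", residues=b),
            SequenceRecord(id="copy", dataset_id="d", residues=a),
        ]
        ab = {"parentA": 10, "parentB": 10, "copy": 1}
        clean, chimeric = detect_chimeras(reads, ab)
        assert chimeric == []

    def test_low_abundance_parents_are_not_considered(self, rng):
        a, b = random_dna(rng, 300), random_dna(rng, 300)
        chim = a[:150] + b[150:]
        reads = [
            SequenceRecord(id="pA", dataset_id="d", residues=a),
            SequenceRecord(id="pB", dataset_id="d", residues=b),
            SequenceRecord(id="q", dataset_id="d", residues=chim),
        ]
        ab = {"pA": 1, "pB": 1, "q": 1}  # parents not 2x more abundant
        _, chimeric = detect_chimeras(reads, ab)
        assert chimeric == []

    def test_planted_chimeras_in_synthetic_dataset(self):
        from culturegap.synthetic_data import SimulationConfig, simulate
        from culturegap.preprocess import TrimSpec, trim_to_anchors

        cfg = SimulationConfig(seed=11, n_datasets=1, reads_per_dataset=2000,
                               chimera_fraction=0.05, revcomp_fraction=0.0,
                               anchorless_fraction=0.0)
        sim = simulate(cfg)
        ds = cfg.dataset_ids[0]
        a5, a3 = sim.truth.anchors[ds]
        spec = TrimSpec(anchor5=a5, anchor3=a3, max_mismatches=2, min_length=50)
        trimmed, _ = trim_to_anchors(sim.datasets[ds], spec)
        # duplicate-count abundances: each unique sequence is its own unit
        dup: dict[str, int] = {}
        for r in trimmed:
            dup[r.residues] = dup.get(r.residues, 0) + 1
        abundances = {r.id: dup[r.residues] for r in trimmed}
        uniq_reads = list({r.residues: r for r in trimmed}.values())
        clean, chimeric = detect_chimeras(uniq_reads, abundances)
        truth = sim.truth.reads.set_index("read_id")["is_chimera"]
        flagged = {r.id for r in chimeric}
        planted = {r.id for r in uniq_reads if truth[r.id]}
        # >=90% of planted chimeras flagged; no clean read flagged
        assert len(flagged & planted) >= 0.9 * len(planted)
        assert not flagged - planted


class TestUniversalOTUs:
    def _cluster(self, rep_id, seq, n, ds):
        return Cluster(rep_id=rep_id, member_ids=[rep_id] + [
            f"{rep_id}_m{i}" for i in range(n - 1)
        ], dataset_id=ds, rep_seq=seq)

    def test_identical_survey_and_cultured_reps_merge(self, rng):
        s = random_dna(rng, 200)
        otus = build_universal_otus(
            {"ds1": [self._cluster("c1", s, 5, "ds1")]},
            [self._cluster("iso1", s, 1, CULTURED_DATASET)],
        )
        assert len(otus) == 1
        assert otus[0].contains_cultured
        assert otus[0].contains_rumen_survey
        assert otus[0].members_by_dataset == {"ds1": 5, CULTURED_DATASET: 1}

    def test_disjoint_representatives_do_not_merge(self, rng):
        seqs = [random_dna(rng, 200) for _ in range(4)]  # ~25% pairwise
        otus = build_universal_otus(
            {"ds1": [self._cluster(f"c{i}", s, 2, "ds1")
                     for i, s in enumerate(seqs[:2])]},
            [self._cluster(f"iso{i}", s, 1, CULTURED_DATASET)
             for i, s in enumerate(seqs[2:])],
        )
        assert len(otus) == 4
        assert sum(o.contains_cultured for o in otus) == 2

    def test_short_representative_excluded_with_warning(self, rng, caplog):
        s = random_dna(rng, 200)
        with caplog.at_level("WARNING"):
            otus = build_universal_otus(
                {"ds1": [self._cluster("c1", s, 3, "ds1"),
                         self._cluster("tiny", random_dna(rng, 20), 1, "ds1")]},
                [self._cluster("iso1", s, 1, CULTURED_DATASET)],
            )
        assert len(otus) == 1
        assert "excluded" in caplog.text

    def test_member_tallies_match_generator_truth(self):
        """3-dataset study, no chimeras: per-OTU per-dataset member counts
        equal the generator's sampled read tallies for the matching taxon."""
        from culturegap.pipeline import (
            PipelineParams, otu_taxon_sets, run_pipeline,
        )
        from culturegap.synthetic_data import (
            REQUIRED_REGION, SimulationConfig, simulate,
        )

        cfg = SimulationConfig(seed=13, n_datasets=3, reads_per_dataset=400,
                               n_cultured_refs=10, n_near_taxa=8,
                               n_novel_lineages=3, chimera_fraction=0.0,
                               revcomp_fraction=0.0)
        sim = simulate(cfg)
        res = run_pipeline(sim.datasets, sim.cultured, sim.reference,
                           params=PipelineParams(required_region=REQUIRED_REGION))
        truth = sim.truth.reads
        kept = truth[truth["has_anchors"]]
        expected = kept.groupby(["taxon_id", "dataset_id"]).size()
        taxa_of = otu_taxon_sets(res, truth)
        seen_taxa = set()
        for otu in res.universal_otus:
            taxa = taxa_of[otu.otu_id]
            if not taxa:
                continue
            assert len(taxa) == 1  # planted lineages are well separated
            (taxon,) = taxa
            seen_taxa.add(taxon)
            for ds in cfg.dataset_ids:
                assert otu.members_by_dataset.get(ds, 0) == int(
                    expected.get((taxon, ds), 0)
                )
        # every sampled taxon surfaced as an OTU
        assert seen_taxa == set(kept["taxon_id"])

    def test_member_sum_equals_tier1_sizes(self, rng):
        seqs = [random_dna(rng, 200) for _ in range(3)]
        ds_clusters = {"ds1": [self._cluster(f"c{i}", s, i + 2, "ds1")
                               for i, s in enumerate(seqs)]}
        cult = [self._cluster("iso0", seqs[0], 1, CULTURED_DATASET)]
        otus = build_universal_otus(ds_clusters, cult)
        total = sum(sum(o.members_by_dataset.values()) for o in otus)
        assert total == sum(c.size for c in ds_clusters["ds1"]) + 1
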