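import numpy as np
import pytest

from tandemscape.codons import random_cds
from tandemscape.molevo import kaks_pair, translate
from tandemscape.salt_response import call_up, classify_genes, count_up_events
from tandemscape.synthio import (
    ConfigurationError,
    PlantedCluster,
    SimConfig,
    evolve_codon_pair,
    generate_expression,
    generate_genome,
    generate_homology_table,
    generate_term_table,
)
from tandemscape.tandem_finder import detect


class TestSimConfig:
    def test_overlapping_clusters_rejected(self):
        with pytest.raises(ConfigurationError, match="overlap"):
            SimConfig(
                planted_clusters=[
                    PlantedCluster(0, 10, 5),
                    PlantedCluster(0, 12, 3),
                ]
            )

    def test_cluster_size_bounds(self):
        with pytest.raises(ConfigurationError, match="size"):
            SimConfig(planted_clusters=[PlantedCluster(0, 0, 10)])
        with pytest.raises(ConfigurationError, match="size"):
            SimConfig(planted_clusters=[PlantedCluster(0, 0, 1)])

    def test_noise_probability_bounds(self):
        with pytest.raises(ConfigurationError):
            SimConfig(background_homology_noise=1.5)


class TestGenerateGenome:
    def test_empty_config_no_homologs(self):
        genes, cds, proteins, manifest = generate_genome(
            SimConfig(n_chromosomes=1, genes_per_chromosome=20, rng_seed=3)
        )
        assert manifest.clusters == [] and manifest.pair_truth == {}
        assert len(genes) == 20

    def test_coordinates_strictly_increasing_nonoverlapping(self):
        genes, *_ = generate_genome(
            SimConfig(n_chromosomes=2, genes_per_chromosome=30, rng_seed=5)
        )
        for chrom in ("chr01", "chr02"):
            chrom_genes = sorted(
                (g for g in genes if g.chromosome == chrom), key=lambda g: g.start
            )
            for a, b in zip(chrom_genes, chrom_genes[1:]):
                assert a.end < b.start

    def test_translations_match_proteins(self):
        _genes, cds, proteins, _m = generate_genome(
            SimConfig(
                n_chromosomes=1, genes_per_chromosome=25, rng_seed=7,
                planted_clusters=[PlantedCluster(0, 4, 3, true_ks=0.5)],
            )
        )
        for gid, seq in cds.items():
            assert translate(seq, gid) == proteins[gid]

    def test_nine_gene_cluster_mutually_alignable(self):
        _g, cds, _p, manifest = generate_genome(
            SimConfig(
                n_chromosomes=1, genes_per_chromosome=20, rng_seed=9,
                planted_clusters=[PlantedCluster(0, 5, 9, true_ks=0.4)],
            )
        )
        [cluster] = manifest.clusters
        members = cluster["members"]
        assert len(members) == 9
        lengths = {len(cds[m]) for m in members}
        assert len(lengths) == 1  # common ancestor, same codon count
        r = kaks_pair(cds[members[0]], cds[members[1]])
        assert np.isfinite(r.Ks)


class TestEvolvePair:
    def test_zero_divergence_returns_ancestor(self, rng):
        anc = random_cds(rng, 120)
        a, b = evolve_codon_pair(anc, 0.0, 0.0, rng)
        assert a == b == anc

    def test_negative_targets_rejected(self, rng):
        anc = random_cds(rng, 120)
        with pytest.raises(ValueError):
            evolve_codon_pair(anc, -0.1, 0.2, rng)
        with pytest.raises(ValueError):
            evolve_codon_pair(anc, 0.5, -0.2, rng)

    def test_ks_recovery_moderate_divergence(self, rng):
        est = []
        for _ in range(60):
            anc = random_cds(rng, 300)
            a, b = evolve_codon_pair(anc, 0.5, 0.2, rng)
            r = kaks_pair(a, b)
            if np.isfinite(r.Ks):
                est.append(r.Ks)
        assert np.mean(est) == pytest.approx(0.5, rel=0.10)

    def test_saturated_divergence_recovered_with_wide_tolerance(self):
        # beyond Ks ~ 2 the JC correction is noisy and many pairs saturate,
        # so recovery is checked on more replicates at a wide tolerance
        rng = np.random.default_rng(2)
        est = []
        for _ in range(150):
            anc = random_cds(rng, 300)
            a, b = evolve_codon_pair(anc, 2.5, 0.2, rng)
            r = kaks_pair(a, b)
            if np.isfinite(r.Ks):
                est.append(r.Ks)
        assert np.mean(est) == pytest.approx(2.5, rel=0.25)

    def test_descendants_stay_stop_free(self, rng):
        anc = random_cds(rng, 150)
        a, b = evolve_codon_pair(anc, 1.0, 0.5, rng)
        assert "*" not in translate(a) and "*" not in translate(b)


class TestHomologyTable:
    def test_three_gene_cluster_complete_graph(self):
        genes, _c, _p, manifest = generate_genome(
            SimConfig(
                n_chromosomes=1, genes_per_chromosome=10, rng_seed=11,
                planted_clusters=[PlantedCluster(0, 2, 3)],
            )
        )
        hits = generate_homology_table(genes, manifest, noise=0.0)
        informative = hits[hits["qseqid"] != hits["sseqid"]]
        pairs = {frozenset((q, s)) for q, s in zip(informative["qseqid"], informative["sseqid"])}
        assert len(pairs) == 3  # complete graph on 3 members
        self_hits = hits[hits["qseqid"] == hits["sseqid"]]
        assert len(self_hits) == len(genes)
        assert (informative["evalue"] < 1e-10).all()

    def test_zero_noise_zero_false_positives(self):
        sim = SimConfig(
            n_chromosomes=2, genes_per_chromosome=40, rng_seed=13,
            planted_clusters=[PlantedCluster(0, 3, 4), PlantedCluster(1, 10, 2)],
        )
        genes, _c, _p, manifest = generate_genome(sim)
        hits = generate_homology_table(genes, manifest, noise=0.0)
        clusters, _ = detect(genes, hits)
        detected = sorted(tuple(sorted(c.members)) for c in clusters)
        planted = sorted(tuple(sorted(c["members"])) for c in manifest.clusters)
        assert detected == planted

    def test_noise_never_bridges_planted_clusters(self, rng):
        sim = SimConfig(
            n_chromosomes=2, genes_per_chromosome=500, rng_seed=17,
            planted_clusters=[
                PlantedCluster(0, 10, 4), PlantedCluster(0, 16, 3),
                PlantedCluster(1, 100, 5),
            ],
        )
        genes, _c, _p, manifest = generate_genome(sim)
        hits = generate_homology_table(genes, manifest, noise=0.01, rng=rng)
        clusters, _ = detect(genes, hits)
        truth = manifest.cluster_of()
        for c in clusters:
            planted_ids = {truth[m] for m in c.members if m in truth}
            assert len(planted_ids) <= 1


class TestExpression:
    def _run(self, class_counts, seed=19, n_genes=60):
        sim = SimConfig(
            n_chromosomes=1, genes_per_chromosome=n_genes, rng_seed=seed,
            planted_clusters=[PlantedCluster(0, 0, 9), PlantedCluster(0, 12, 9)],
            planted_class_counts=class_counts,
        )
        genes, _c, _p, manifest = generate_genome(sim)
        counts, design, lengths, de = generate_expression(sim, manifest)
        return manifest, counts, design, lengths, de

    def test_null_design_zero_up_calls(self):
        _m, _counts, _design, _lengths, de = self._run({})
        assert call_up(de)["up"].sum() == 0

    def test_planted_leaf_gene_counts_five_events(self, rng):
        sim = SimConfig(
            n_chromosomes=1, genes_per_chromosome=10, rng_seed=23,
            planted_class_counts={"leaf_specific": 1},
        )
        genes, _c, _p, manifest = generate_genome(sim)
        [gid] = list(manifest.gene_classes)
        counts, design, lengths, de = generate_expression(sim, manifest)
        events = count_up_events(call_up(de))
        assert events.loc[gid, "leaf"] >= 4 and events.loc[gid, "root"] <= 1

    def test_classifier_recovers_planted_classes(self):
        target = {"leaf_specific": 5, "root_specific": 7, "co_expressed": 6}
        manifest, _counts, _design, _lengths, de = self._run(target)
        labels = classify_genes(count_up_events(call_up(de)))
        recovered = labels.set_index("gene_id")["label"].to_dict()
        for gid, planted in manifest.gene_classes.items():
            assert recovered[gid] == planted

    def test_counts_shape_and_design(self):
        _m, counts, design, lengths, _de = self._run({}, n_genes=30)
        assert counts.shape == (30, 2 * 2 * 5 * 3)
        assert set(design["condition"]) == {"control", "treatment"}
        assert (lengths > 0).all()


def test_term_table_contains_planted_overlap():
    sim = SimConfig(
        n_chromosomes=1, genes_per_chromosome=80, rng_seed=29,
        planted_clusters=[PlantedCluster(0, 0, 9), PlantedCluster(0, 20, 9),
                          PlantedCluster(0, 40, 9)],
        planted_terms=[("GO:X", 20, 15)],
        n_null_terms=5,
    )
    genes, _c, _p, manifest = generate_genome(sim)
    table = generate_term_table(sim, manifest)
    study = {g for c in manifest.clusters for g in c["members"]}
    planted = table[table["term_id"] == "GO:X"]
    assert len(planted) == 20
    assert len(set(planted["gene_id"]) & study) == 15
    assert manifest.enriched_terms == ["GO:X"]
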