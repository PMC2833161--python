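"""Term annotation of a protein cluster.

Implants a keyword into 8 of 200 proteins, makes those 8 a topic
cluster, then annotates the cluster: hypergeometric enrichment
(Bonferroni-corrected within each category) for categorical terms, and
entropy×idf scoring for literature unigrams/bigrams.  The implanted
keyword should come out on top with a vanishing p-value.
"""

from envclust.annotate import annotate_cluster
from envclust.synthdata import CorpusGenSpec, gen_corpus

cluster = [f"s{i:03d}" for i in range(8)]
corpus, _ = gen_corpus(
    CorpusGenSpec(
        n_proteins=200,
        clusters={0: cluster},
        implants={"keyword": {"zinc-binding": cluster}},
        seed=0,
    )
)

results = annotate_cluster(cluster, corpus)
for category in sorted(results):
    print(f"[{category}] {len(results[category])} significant terms")
    for t in results[category][:3]:
        extra = "" if t.entropy_score is None else f"  entropy={t.entropy_score:.2f}"
        print(f"  {t.term}: k={t.k}/{t.n}, background {t.K}/{t.M}, "
              f"corrected p={t.p_corrected:.2e}{extra}")
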