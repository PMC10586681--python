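# coopnet

Signed co-occurrence network analysis of free-word associations.

`coopnet` is a pipeline for studies that elicit **free-word associations**
(here: five words per participant about "the excessive activity that bothers
you the most"), tag each association with two emotion labels from a fixed
20-item affect schedule, and record the substance or behavior the
participant had in mind plus a 4-level problem-intensity rating.  From such
a response table the pipeline extracts **mental representations** — clusters
of associations that travel together across participants — and relates them
to misuse type, problem intensity and emotional tone.  It is aimed at
researchers in addiction science and psycholinguistics who want the full
chain, from raw survey rows to inferential statistics, as tested,
scriptable code.

## Method

1. **Preprocessing.**  Tokens are lower-cased, accent-stripped and merged
   through a user-supplied synonym map; participants who chose the "other"
   category are excluded; tokens mentioned by fewer than 10 participants
   are treated as idiosyncratic and dropped; participants left with no
   retained tokens are excluded; emotion labels provided by fewer than 50%
   of participants are set aside.

2. **Signed network.**  For every retained token pair the 2×2
   participant-level contingency table is scored with the log-likelihood
   ratio (Dunning's G) against independence,

   $$G = 2 \sum_{\text{cells}} O \ln(O/E),$$

   signed **+G** if the pair co-occurs more often than chance (attractive)
   and **−G** if less often (repulsive).

3. **Modules.**  Partitions are scored with the signed extension of
   modularity,

   $$Q = \frac{1}{2(v^+ + v^-)} \sum_{ij}\left[(w^+_{ij} - e^+_{ij}) - (w^-_{ij} - e^-_{ij})\right]\delta_{M_i M_j},$$

   where $e^\pm_{ij} = s^\pm_i s^\pm_j / 2v^\pm$ is the sign-separated
   configuration-model expectation.  A signed Louvain optimizer is run many
   times; modules are fixed by **consensus clustering**: the run-by-run
   co-classification matrix is thresholded (default 40%) and re-clustered
   until all runs agree.

4. **Profiling and inference.**  Each participant is linked to the module
   holding the plurality of their retained associations.  Modules are
   profiled by member tokens, relative emotion-label percentages and
   positive/negative affect shares, and tested with chi-square tests of
   independence (module × misuse type, module × intensity), Kruskal–Wallis
   H tests on per-participant label counts, and Dunn pairwise z tests.

Because raw survey data of this kind is typically not shareable, the
package ships a **synthetic generator** that plants known module structure
(home-module concentration, Zipf token popularity, module-coupled emotion,
category and intensity distributions) so every stage can be validated
against ground truth.

## Worked example

```python
from coopnet import PipelineConfig, run_pipeline, score_recovery
from coopnet.simulate import SyntheticConfig, generate_corpus

corpus, truth = generate_corpus(SyntheticConfig(seed=1))   # 546 participants
result = run_pipeline(corpus, PipelineConfig(random_seed=1))

print(result.network.n_nodes, result.partition.n_modules,
      round(result.consensus.modularity, 4))
print(result.retained_labels)
m = result.misuse_test
print(f"chi2={m.chi2:.1f}, df={m.df}, N={m.n}, p={m.p_value:.3g}")
print(score_recovery(truth, result.partition, result.assignments))
```

prints

```
70 4 0.4044
['joy', 'calmness', 'worries', 'shame', 'anxiety', 'contempt']
chi2=48.7, df=3, N=546, p=1.5e-10
{'token_ari': 1.0, 'n_tokens_scored': 70,
 'participant_ari': 0.8909, 'n_participants_scored': 546}
```

Reading: of the 77 planted tokens, 70 survive the rare-token filter and
the consensus partition recovers the four planted modules exactly
(token ARI = 1).  Six emotion labels clear the 50% provision threshold.
Module membership is strongly coupled to misuse type
(χ², df = 3, N = 546), and plurality assignment recovers 89% of the
participants' latent home modules (ARI 0.89 — imperfect because each
participant draws a fifth of their associations from foreign modules).

The same run is available from the shell:

```bash
coopnet run-all --seed 1 --outdir out/
```

which writes the simulated responses, the filtered corpus and filter
report, the signed network (GraphML + edge list), the consensus
co-classification matrix, the partition, module profiles, participant
assignments and the statistical report.

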