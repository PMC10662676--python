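# cfa — corpus framework analysis

`cfa` is a toolkit for **corpus framework analysis**: combining
corpus-linguistics statistics with a qualitative coding frame to study
how a population — here, forum users who self-report a mental-health
diagnosis — talks about a concept such as *personal recovery* (living a
satisfying, hopeful life despite illness-related limitations, as
opposed to symptom-focused clinical recovery).

It is written for computational social scientists and health
researchers who have (or simulate) a large collection of
user-attributed forum posts and want a reproducible, scriptable version
of the classic keyword/concordance/collocation workflow, from raw posts
to extrapolated category frequencies.

## What it computes

1. **Cohort detection** — users with a first-person diagnosis
   statement ("I was diagnosed with bipolar"), via a configurable
   template family.
2. **Corpus construction** — restrict to condition-specific subforums
   and condition-mentioning posts, score each post's similarity to a
   concept term list by TF-IDF-weighted cosine similarity, and split
   into a high-relevance *target* corpus and low-relevance *reference*
   corpus by score cutoffs plus a 94-word minimum length.
3. **Keyness** — for each lemma with frequencies *a*, *b* in corpora of
   sizes *c*, *d*, the log-likelihood statistic G² (likelihood-ratio G
   for the 2×2 table [[a, c−a], [b, d−b]]). A lemma is *key* iff it is
   overused at least twice ((a/c)/(b/d) ≥ 2), significant at
   α = 10⁻⁴ (G² above the χ²₁ quantile ≈ 15.13), and used by ≥ 5% of
   target-corpus users.
4. **Concordance coding** — KWIC lines with 20-word contexts, sorted
   and randomly sampled (30 per key lemma) for human coding against a
   two-level frame (the POETIC personal-recovery frame ships with the
   package); coded label shares are extrapolated to corpus-level
   category frequencies, conserving total mass exactly under
   single-label coding.
5. **Collocation** — content-word collocates within ±5 words, minimum
   co-occurrence 5, ranked by cubed mutual information
   MI³ = log₂(O³·N / (f₁·f₂·W)).
6. **Coder agreement** — Cohen's κ = (p_o − p_e)/(1 − p_e), plus the
   inverse solver recovering p_e from a published (p_o, κ) pair.

Because real self-reported-diagnosis forum datasets are
access-restricted, the package includes a **synthetic corpus
generator** that plants every signal the pipeline is supposed to
recover (relevant posts enriched in concept terms, self-reporter users,
condition mentions, collocation pairs) with full ground truth, so every
stage is testable end to end. See `docs/methods.md` for the models,
defaults and limitations.

## Worked example

```python
from cfa import SynthConfig, TermList, generate, run_pipeline
from cfa.synthetic_data import default_planted_terms
from cfa.collocation import collocates

cfg = SynthConfig(seed=55, self_report_fraction=0.6,
                  condition_mention_rate=0.7, words_per_post=(80, 160),
                  subforum_probs=(0.5, 0.3, 0.1, 0.1))
corpus, truth = generate(cfg)
result = run_pipeline(corpus,
                      term_list=default_planted_terms(),
                      condition_terms=TermList([("bipolar",)]),
                      allowed_subforums={"bipolar", "bipolarreddit"},
                      min_words=80)
```

With INFO logging on, the run prints the flow-chart counts:

```
all posts                   2072 posts     200 users
self-report cohort          1268 posts     124 users
condition subforums          995 posts     124 users
condition mentions           725 posts     124 users
target corpus                145 posts      86 users
reference corpus             362 posts     115 users
key lemmas: 26 of 3697 in union vocabulary
```

Each stage narrows the corpus: 200 simulated users shrink to the 124
who self-report a diagnosis, then to their posts in the two condition
subforums that mention the condition; score quantiles split those into
a 145-post target and 362-post reference corpus. The top key lemmas:

```
lemma            a     b   ratio        G2  users%
prfababa       141    52    5.99     143.2   70.9%
prbebaba       137    51    5.93     138.3   76.7%
prdobaba       145    63    5.08     130.5   75.6%
```

All 26 key lemmas are planted concept-term lemmas (`pr…` pseudo-words)
or their planted collocates — the ratio column shows they occur 5–6×
more often per word in the target, G² far above the 15.13 gate, and
each is used by ~3/4 of target users. Collocates of the strongest key
lemma, ranked by MI³:

```
prfababa ~ bababa: O=132 f2=1806 MI3=14.08
prfababa ~ bebaba: O=48  f2=758  MI3=10.96
```

The same steps are available from the shell via the `cfa` command
(`cfa simulate`, `cfa cohort`, `cfa filter`, `cfa score`, `cfa split`,
`cfa keyness`, `cfa absent`, `cfa concordance`, `cfa sample-coding`,
`cfa extrapolate`, `cfa collocate`, `cfa kappa`); every table is TSV
with provenance metadata, posts are JSONL.

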