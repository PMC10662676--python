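# Methods

This note documents the models, statistics and design choices behind
`cfa`, and what the synthetic-data experiments do and do not show.

## The analysis in one paragraph

Given a large collection of user-attributed forum posts, the pipeline
(1) identifies a cohort of users who state a diagnosis in the first
person; (2) restricts to posts in condition-specific subforums that
mention the condition; (3) scores each remaining post's similarity to a
curated concept term list by TF-IDF-weighted cosine similarity and
splits the posts into a high-relevance *target* corpus and a
low-relevance *reference* corpus; (4) contrasts the two corpora to find
*key lemmas* — words significantly overused in the target — which are
then read in context (KWIC concordances), coded against a two-level
qualitative frame, and extrapolated back to corpus-level category
frequencies; collocation and coder-agreement statistics support that
qualitative layer.

## Normalization layer

All statistics count **lemmas** (dictionary forms: "recovering",
"recovered" → "recover") over **word tokens** (alphabetic/alphanumeric
tokens; punctuation, URLs and user mentions are excluded and never
contribute to word counts or break-free multiword matches).

The analyzer is pluggable (any object with `analyze(text)` plus
`name`/`version`); the default `RuleAnalyzer` is a deterministic
regex tokenizer with a small irregular-form table, suffix-stripping
rules for regular inflection, and a 5-class POS tagger
(NOUN/VERB/ADJ/ADV/OTHER). Only the content/function distinction
matters downstream (the collocation filter), so the coarse tagger is
sufficient. Intra-word hyphens are treated as separators ("self-care"
≡ "self care"), so hyphenation does not block phrase matching. The
analyzer identity is recorded in the metadata of every output table:
absolute score cutoffs are only meaningful relative to a fixed
normalization.

Multiword term matching is greedy left-to-right longest-match over
lemma sequences, with 0-based end-exclusive token spans everywhere.
Matched spans never overlap; any non-word token breaks a multiword
span.

## Relevance scoring and the corpus split

Each post is represented as a vector over term-list entries with weight
tf(term, post) · idf(term), where tf is the match-span count and
idf(term) = ln((1+N)/(1+df)) + 1 over the scored corpus (the smoothed
variant that keeps unseen terms finite). The query vector holds the idf
weights; the score is the cosine of the two vectors, in [0, 1], zero
exactly when the post shares no term with the list, and invariant to
post length scaling. The tf/idf/query variants are deliberate,
recorded choices: "TF-IDF cosine" alone underdetermines the score, and
cutoffs are only transferable given the exact weighting.

The split takes posts **strictly above** the upper cutoff (default
0.025) as the target and **strictly below** the lower cutoff (default
0.013) as the reference, both gated to a minimum length of 94 words
(inclusive). Posts between the cutoffs belong to neither. The length
gate is applied at split time, not before scoring, so calibration
samples can include short posts. The default cutoffs were calibrated
on the original restricted dataset and do not transfer to other corpora
or weightings; for synthetic corpora the pipeline can instead derive
cutoffs from score quantiles (default: 80th/50th percentile), which
mirrors the decile-coding calibration design. `decile_sample`
partitions scores into 10 equal-count quantile bins and samples
`per_decile` posts per bin, merging consecutive bins whose scores are
all identical (a zero-inflated bottom contributes one bin's worth in
total, e.g. 90 ids from 1000 scores whose bottom fifth is zero).

## Keyness

For lemma frequencies a (target) and b (reference) with corpus word
totals c and d, the significance statistic is the likelihood-ratio G²
for the 2×2 table [[a, c−a], [b, d−b]] with margin-derived expected
counts and the convention O·ln(O/E) = 0 at O = 0 (no smoothing). For
rare lemmas this coincides with the familiar two-cell corpus-linguistics
shorthand 2·(a·ln(a/E₁) + b·ln(b/E₂)). The gate at significance level
α = 10⁻⁴ is the chi-square(1) upper quantile (≈15.13), computed from
the distribution at call time — never a hard-coded constant.

A lemma is **key** iff, jointly:

* a/c > b/d (overused in the target at all),
* overuse ratio (a/c)/(b/d) ≥ 2, with the zero reference cell smoothed
  as b := 0.5 *for the ratio only*,
* G² ≥ the α gate,
* used by ≥ 5% of target-corpus users (dispersion guard against one
  prolific author; the denominator is the target corpus user count).

No multiple-testing correction is applied beyond the stringent α.
Absent concept terms are reported separately: *missing* (zero target
frequency) and *underused* (positive target frequency but lower relative
frequency than the reference); multiword term frequencies are
match-span counts.

## Concordances, coding and extrapolation

A concordance line holds one node-lemma occurrence with up to 20 word
tokens of context on each side, truncated at post boundaries. Sorting
is by node lemma, then left context read outward from the node
(nearest word first), then right context, with a stable sort. Coding
samples are uniform without replacement (default 30 lines per lemma),
seeded. Coded labels enter through a TSV file interface — assigning
categories is human work, not computed.

Extrapolation scales each lemma's coded label shares up to its corpus
frequency: category c gains F(ℓ)·(#lines labeled c)/n(ℓ). Arithmetic
is exact-rational (`fractions.Fraction`), so under single-label coding
total category mass equals Σ F(ℓ) *exactly*. Multi-label lines give
each label full proportional mass (totals can then exceed Σ F); lines
outside the frame carry the reserved label `Not-frame`, which forms its
own pseudo-domain.

## Collocation

Collocates of a node are content-word lemmas within a symmetric window
of 5 word positions (punctuation skipped, windows truncated at post
boundaries), with observed count O ≥ 5, ranked by cubed mutual
information MI³ = log₂(O³/E) with E = f₁·f₂·W/N, W = 2·window. The
inclusion of W in E follows common corpus-linguistics convention and is
recorded in output metadata. A token near two node occurrences counts
once (union semantics), and node occurrences are never collocates of
themselves.

## Coder agreement

Cohen's κ = (p_o − p_e)/(1 − p_e) with p_e from the coders' label
marginals, unweighted, binary or multi-class. Because published
agreement figures often omit the confusion table, the package also
inverts the formula (p_e = (p_o − κ)/(1 − κ)) so reported (p_o, κ)
pairs can be checked for internal consistency.

## Synthetic corpora

The generator emulates the statistical skeleton of a forum dataset at
desk scale: posts are bags of pseudo-word lemmas from a Zipfian
background vocabulary (default 5000 lemmas, exponent 1.1) plus a closed
function-word set, rendered as lowercase sentences. Defaults: 200
users, 5–15 posts each, 50–150 words per post (≈2×10⁵ word tokens per
corpus); 20% of posts are *relevant* and carry the 20 planted concept
terms (16 single words, 4 two-word phrases) at 4× their background
per-slot rate of 0.002 per term; 10% of users receive one first-person
diagnosis sentence; 40% of posts mention the condition term; two
planted collocation pairs insert a dedicated collocate within 5 word
positions of its node at rate 0.5. Pseudo-lemmas are built from open
syllables so they are fixed points of the default lemmatizer, with
suffixes cueing a coarse POS so the content-word filter is exercised.
Generation is fully deterministic under the seed.

What the generator does **not** emulate: grammar and word order,
realistic topic structure, spelling variation, author style, bursty
word re-use within threads, or human coding disagreement. Passing
recovery experiments therefore show that the statistics isolate
frequency signals of the planted kind at realistic corpus sizes — not
that the pipeline's qualitative conclusions transfer to any particular
real forum.

## Experiment sizes and numerical choices

* Null (false-positive) calibration: 200 replicate corpora of ≈2×10⁵
  tokens with enrichment 1; the G²-gate pass fraction is averaged over
  replicates, as is the full-conjunction key-lemma count.
* Planted-keyword recovery: 20 seeds, 20 single-lemma terms at
  enrichment 4, target/reference split by generated labels.
* Ranking separation: the probability that a random relevant post
  outscores a random background post (Mann-Whitney AUC).
* Oracle equivalences: G² vs an independent contingency G-test on 10⁴
  random tuples at 1e-9; collocation vs a naive per-position window
  scan on a ≤10⁴-token corpus at 1e-9.
* Ties: keyness results sort by G² descending then lemma; collocates by
  MI³ descending then lemma; concordance sorting is stable.
* Degenerate inputs: empty corpora, empty term lists, empty pattern
  sets and empty split sides are hard errors; absent node/lemma queries
  return empty results with warnings.

## Known limitations

The default lemmatizer is a small rule system, not a dictionary
lemmatizer; out-of-inventory irregular forms fall back to suffix
stripping, which can under- or over-stem rare English words (the
analyzer interface accepts a richer drop-in replacement). Self-report
detection is surface-level template matching: it does not handle
negation ("I was never diagnosed…") or reported speech beyond what the
template family excludes. The published score cutoffs are not
meaningful for corpora other than the one they were calibrated on.
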