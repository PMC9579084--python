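# inbuilt-rubric

Rubric-mapped semantic spaces for automated scoring of constructed
responses (summaries, short essays), with a full psychometric
validation battery.

## The problem

Latent semantic analysis (LSA) represents words and documents as
vectors in a `k`-dimensional space obtained by log-entropy weighting a
term–document matrix and truncating its singular value decomposition
(term vectors are the rows of **U·S**). Projecting a student summary
into such a space says *how similar* it is to other texts, but the
latent dimensions mean nothing by themselves, so content scoring
normally requires comparison against gold summaries.

The **Inbuilt Rubric** method instead rotates the latent space so that
its leading dimensions *are* the concepts of an assessment rubric. A
new basis **β** is assembled whose first `k` columns are unit *concept
vectors* — normalized sums of the term vectors of a few expert-chosen
lexical descriptors (classic variant) or of all nouns in a fragment of
the instructional text (fragment variant) — and whose remaining columns
are standard-basis vectors drawn at random without replacement. **β**
is orthonormalized by modified Gram–Schmidt; a per-column *fidelity*
(uncentered correlation between each meaningful column before and after
orthogonalization, gated at 0.80) certifies that a concept dimension
still means its concept. Because the final basis is orthonormal, the
change of basis is a pure rotation: every norm and pairwise cosine of
the original space is preserved. A document folded into the rotated
space then scores each rubric concept directly as its leading
coordinates.

The **bifactor** variant adds one general-knowledge dimension: each
concept's lemma list is split into two balanced subsets, each subset
becomes a unit vector, a one-factor analysis of the `2k` subset vectors
yields loadings `λ`, and the general vector is the normalized
loadings-weighted sum `G = Σ λᵢ·Dimᵢ`. Placed first in **β** (an order
this package exposes alongside the after-the-concepts layout), it
residualizes every concept dimension against shared meaning, mirroring
a bifactor measurement model.

Validation follows standard psychometrics: two-way mixed-effects
intraclass correlations for inter-rater reliability, Horn's parallel
analysis (95th-percentile Monte Carlo thresholds) and
maximum-likelihood/oblimin exploratory factor analysis for the human
ratings, standardized-β multiple regressions of human concept scores on
the computational scores, and unweighted-least-squares CFA/SEM with
full cross-loadings between computational and human concept factors
(classic and bifactor structural forms). All of these are implemented
in `inbuilt_rubric.psychometrics` on numpy/scipy.

A seeded synthetic-data module (`inbuilt_rubric.fixtures`) generates
planted-topic corpora, rubrics, summaries with known concept coverage,
and simulated raters with calibrated reliability, so the entire
pipeline is testable without any external corpus.

## Worked example

Simulate a study (5 topics, 60 training paragraphs per topic, 100
summaries, 2 raters at reliability 0.8), train a 25-dimensional space,
map the rubric onto it, score the summaries and validate:

```bash
inbuilt-rubric simulate --out demo --seed 3 --docs-per-topic 60 \
    --words-per-topic 30 --summaries 100
inbuilt-rubric train --corpus demo/corpus.txt --out demo/space --k 25 --seed 3
inbuilt-rubric transform --space demo/space --rubric demo/rubric.yaml \
    --seed 3 --out demo/mspace
inbuilt-rubric score --mspace demo/mspace --docs demo/summaries.txt \
    --out demo/scores.csv
inbuilt-rubric validate --scores demo/scores.csv --ratings demo/ratings.csv \
    --out demo/report.json
```

The transform step prints the fidelity of each meaningful dimension —
all well above the 0.80 gate here:

```
meaningful space -> demo/mspace (fidelity: concept_1=1.000,
  concept_2=0.984, concept_3=0.972, concept_4=0.966, concept_5=0.963)
```

`demo/scores.csv` holds one row per summary; `score__concept_j` is the
summary's raw coordinate on concept `j` (unnormalized, so longer
summaries score higher, as raw content coverage should):

```
doc_id,score__concept_1,score__concept_2,...,oov_rate,flagged
summary000000,60.1189815174,74.0142305865,...,0,0
summary000001,59.6318238999,45.2197338539,...,0,0
```

The validation report shows the simulated raters landing on their
reliability target and the cross-loading SEM flagging, for every human
concept factor, the matching computational score as its strongest
standardized path (convergent validity with no misses):

```
icc: {'concept_1': 0.791, 'concept_2': 0.844, 'concept_3': 0.771,
      'concept_4': 0.858, 'concept_5': 0.776, 'total': 0.874}
sem convergent paths: {'HR_concept_1': 'ir__concept_1', ...,
                       'HR_concept_5': 'ir__concept_5'}
```

The same pipeline is available as a library (`run_pipeline(config)`)
with deterministic, byte-identical artifacts for a given config and
seed; see `inbuilt_rubric/scoring.py`.

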