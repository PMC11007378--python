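# xlcui — cross-lingual clinical concept extraction, compared at the document level

Clinical NLP is strongest in English: bigger terminologies, better
pretrained models, more annotated corpora. For notes written in another
language there are two competing strategies: build a **native** pipeline
(annotate a little data, train in-language), or **translate first** and use
off-the-shelf English tools. `xlcui` implements both routes end-to-end and
the evaluation that makes them comparable, for anyone studying when a
translation step is good enough — and when it silently is not.

A document is reduced by each route to the set of distinct concept unique
identifiers (CUIs, e.g. `C0013516`) it mentions, drawn from a UMLS-style
terminology restricted to four semantic groups (CHEM, DEVI, DISO, PROC).
Comparing CUI *sets* per document avoids cross-language span alignment
entirely. The three axes are:

| axis | route |
|---|---|
| `axis1` | native: nested span NER → cosine-softmax normalization |
| `axis2_1` | translate → NER on the translation → normalization |
| `axis2_2` | translate → greedy longest-match dictionary extractor/linker |

The core machinery, all in `src/xlcui/`:

* **nested NER** — every span `(i, j, label)` up to a maximum length gets an
  independent sigmoid score; spans above 0.5 are kept, nesting included.
  Encodings combine a learned mix of the last 4 layers of a small contextual
  stack, a static word vector and a max-pooled char-CNN; spans are read by a
  3-layer LSTM with learned layer weighting; training is binary
  cross-entropy with Adam (on a numpy autodiff core — no GPU, no framework);
* **normalization** — terms embed to unit vectors, CUIs are ranked by
  cosine with softmax training in two phases (train encoder + CUI vectors on
  primary-language-covered concepts; freeze encoder, fit rows for the rest),
  then a semantic-group filter picks the first in-group CUI in the top *k*;
* **translation** — pluggable translator contract with a deterministic
  dictionary translator whose noise modes reproduce documented MT failure
  classes on clinical text (over-literal translations, untranslated
  abbreviations), plus per-sentence smoothed BLEU;
* **evaluation** — mention-level P/R/F1 per group, normalization accuracy on
  gold mentions, document-level CUI-set macro P/R/F1 with empirical
  bootstrap 95% CIs;
* **synthetic data** — a bilingual terminology/corpus/translation generator
  (near-synonym CUI pairs, source-only abbreviations, nested mentions) that
  stands in for restricted corpora and the licensed terminology.

## Worked example

```python
from xlcui.benchmark import BenchmarkConfig, run_benchmark
from xlcui.pipeline import compare_axes

models, sweep = run_benchmark(BenchmarkConfig(seed=1))
print(compare_axes(list(sweep[0.2].values())).to_string(index=False))
```

prints (seed 1, default noise `p_literal=0.2`):

```
   axis  precision  recall       f1       f1_ci  winner
  axis1        1.0 1.00000 1.000000 (1.00-1.00)    True
axis2_1        1.0 0.85625 0.918001 (0.87-0.97)   False
axis2_2        1.0 0.85625 0.918001 (0.87-0.97)   False
```

Reading: on the 8 held-out synthetic documents the native route recovers
every gold CUI set exactly (F1 1.0), while both translated routes lose
recall — literal-translation corruption and untranslated abbreviations
prevent some mentions from being found or linked after translation. Raising
the literal-noise rate widens the gap (`analysis/04_compare_axes.py` prints
the sweep: the axis1-minus-axis2 F1 gap grows from ~0.02 at `p_literal=0`
to ~0.12–0.16 at `p_literal=0.4`), which is the directional conclusion the
pipeline exists to measure.

The numbered drivers under `analysis/` run the same study stepwise and write
tables under `results/`:

```bash
python analysis/01_generate_data.py   --seed 1   # terminology + standoff corpus + split
python analysis/02_train_models.py    --seed 1   # two recognizers + normalizer index
python analysis/03_evaluate_stages.py --seed 1   # per-stage metrics (NER table, norm acc, BLEU)
python analysis/04_compare_axes.py    --seed 1   # end-to-end axis comparison
```

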