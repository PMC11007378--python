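#!/usr/bin/env python
"""Generate the synthetic study data: bilingual terminology, annotated
source-language corpus, and the 80/20 train/test split.

Writes the terminology (pipe-delimited), the corpus in BRAT standoff
(.txt/.ann pairs, split into train/ and test/), and a summary of what was
generated.
"""

import argparse
import json
from dataclasses import asdict
from pathlib import Path

from xlcui.documents import write_standoff
from xlcui.synthetic import (GenConfig, build_lexicon, generate_corpus,
                             generate_terminology, is_abbreviation, split_corpus)
from xlcui.terminology import save_terminology


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()

    cfg = GenConfig(seed=args.seed)
    terminology = generate_terminology(cfg)
    docs = generate_corpus(terminology, cfg)
    train, test = split_corpus(docs, 0.8, seed=args.seed + 11)
    lexicon = build_lexicon(terminology)

    args.out.mkdir(parents=True, exist_ok=True)
    save_terminology(terminology, args.out / "terminology.psv")
    write_standoff(train, args.out / "train")
    write_standoff(test, args.out / "test")
    with (args.out / "lexicon.tsv").open("w", encoding="utf-8") as fh:
        for src, tgt in sorted(lexicon.items()):
            fh.write(f"{src}\t{tgt}\n")
    (args.out / "gen_config.json").write_text(
        json.dumps(asdict(cfg), indent=2) + "\n")

    n_mentions = sum(len(d.mentions) for d in docs)
    n_abbrev = sum(1 for _, _, lang, t in terminology.iter_terms({"FRE"})
                   if is_abbreviation(t))
    print(f"terminology: {len(terminology)} concepts, "
          f"{sum(1 for _ in terminology.iter_terms())} terms "
          f"({n_abbrev} source-only abbreviations)")
    print(f"corpus: {len(docs)} documents, {n_mentions} gold mentions")
    print(f"split: {len(train)} train / {len(test)} test -> {args.out}")


if __name__ == "__main__":
    main()
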