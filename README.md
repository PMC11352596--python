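# gazelink

Gazetteer-based biomedical entity linking: dense candidate retrieval over
term embeddings plus a temperature-scaled cosine-softmax classification head
whose per-concept weights are initialized as the mean embedding of all terms
mapped to that concept, fine-tuned over a frozen embedding backend. Includes
span-level NER ensemble utilities (sentence splitting, IOB coding, majority
voting), a top-k evaluation harness, and a synthetic-data module so the whole
pipeline is testable offline.

## Layout

| module | contents |
| --- | --- |
| `gazelink.kb_io` | gazetteer / mention-annotation TSV dialects, training-set construction, stratified splits |
| `gazelink.embedding` | embedding-backend contract, deterministic char-n-gram hashing backend, matrix text serialization |
| `gazelink.retrieval` | exact cosine term index, per-code max dedup, top-k candidate lists |
| `gazelink.head` | centroid-initialized cosine-softmax head: logits, posteriors, top-k prediction, mini-batch fine-tuning, serialization |
| `gazelink.ner_ensemble` | offset-preserving sentence segmentation, IOB encode/decode, exact-span majority voting |
| `gazelink.evaluation` | strict-span P/R/F1, top-k accuracy, per-semantic-tag breakdowns |
| `gazelink.synth` | planted-embedding generators for gazetteers, mentions, NER corpora |

## CLI

Everything is reachable through the `gazelink` entry point and runs offline
with the built-in hashing embedder:

```bash
gazelink simulate --preset small --seed 1 --out corpus/      # synthetic corpus
gazelink validate corpus/gazetteer.tsv
gazelink split --val-fraction 0.25 --seed 7 \
    --in corpus/mentions_train.tsv --out-train tr.tsv --out-val va.tsv
gazelink link --gazetteer corpus/gazetteer.tsv \
    --mentions corpus/mentions_val.tsv --k 200 --out candidates.tsv
gazelink train-head --train corpus/mentions_train.tsv \
    --gazetteer corpus/gazetteer.tsv --tau 0.05 --lr 3e-4 --epochs 20 \
    --seed 0 --out head.txt
gazelink predict --head head.txt --mentions corpus/mentions_val.tsv \
    --k 200 --out predictions.tsv
gazelink eval-nel --gold corpus/mentions_val.tsv --candidates candidates.tsv \
    --ks 1,5,25,50,100,200 --by-tag --gazetteer corpus/gazetteer.tsv
gazelink vote --members m1.tsv --members m2.tsv --members m3.tsv --out voted.tsv
gazelink eval-ner --gold corpus/ner_gold.tsv --pred voted.tsv
```

File dialects are tab-separated with headers: gazetteers carry
`code/language/term/semantic_tag/mainterm`, annotations carry
`filename/label/start_span/end_span/text[/code]` with `+`-joined composite
codes and the sentinel `NO_CODE` for uncoded mentions. Offsets are 0-based,
half-open.

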