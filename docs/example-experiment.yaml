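# Example config for `quorum experiment --config docs/example-experiment.yaml`
# Generate the corpus first:  quorum synth --out corpus.jsonl --seed 1
corpus_path: corpus.jsonl
workdir: runs/demo
ratios: [0.8, 0.1, 0.1]
seed: 1
n_subsets: 3
architectures: [textcnn, fasttext, dpcnn]
strategy: independent_sample
mask: false
clean: true
baselines: [single, oversample, undersample, hierarchical]
min_posts_per_user: 3
train_overrides: {}
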