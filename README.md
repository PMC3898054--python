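# consnet

Weighted consensus trees and explicit weighted consensus networks from
collections of gene trees.

Given gene trees whose internal branches carry supports (bootstrap percent or
posterior probabilities) and, optionally, per-tree weights, `consnet`:

* computes overall cluster (bipartition) weights — from branch supports, from
  tree weights, or from both — and ranks all clusters;
* builds four consensus trees: support-based majority rule, support-based
  extended majority rule, support-based Nelson (maximum-weight clique of
  compatible clusters, exact search), and weight-based extended majority rule;
* builds explicit weighted consensus networks: a backbone tree (weight-based
  consensus tree, or a supplied rooted species tree) plus directed, weighted
  reticulation branches for every remaining cluster above a weight cutoff that
  is one subtree-prune-and-regraft (SPR) move away from the current network
  state; transfer direction is decided by support-weighted cumulative
  Robinson–Foulds distances between the two SPR interpretations and the gene
  trees containing the united cluster;
* detects intragenic recombination / partial transfers with a sliding-window
  scan over a multiple sequence alignment, annotating each event with the
  merged interval span of the windows supporting it;
* ships a self-contained neighbor-joining + bootstrap fallback (p-distance,
  JC69, K2P) so the pipeline runs without external inference programs, while
  externally produced per-window Newick trees remain first-class inputs;
* simulates benchmark data (random clock-deviated trees, HKY+Γ sequences,
  injected recombination blocks) and scores detected events as true/false
  positives against the known truth.

## Command line

All subcommands write results plus a JSON run manifest into `--out`:

```sh
consnet make-fixtures --out fixtures          # worked-example trees + a small simulated set
consnet consensus fixtures/three_trees.nwk --method bem --out out
consnet network fixtures/three_trees.nwk --cutoff 10 --out out
consnet hgt genes.nwk --species-tree species.nwk --cutoff 30 --out out
consnet scan aln.fasta --window-frac 0.5 --step 5 --cutoff 10 --seed 1 --out out
consnet scan aln.fasta --window-frac 0.5 --method external --external-trees dir/ --seed 1 --out out
consnet infer-nj aln.fasta --model jc69 --bootstrap 100 --seed 1 --out out
consnet simulate --taxa 16 --events 2 --block-frac 0.25 --seed 1 --out sim
consnet evaluate sim/true_events.tsv out/reticulations.tsv --tree sim/true_tree.nwk --out eval
```

Tree-list files hold one Newick per line with an optional leading
`weight=<float>` token (tab-separated) for per-tree weights. Supports are
read from internal node labels (or `[&support=..]` comments); probabilities
are detected automatically and scaled to percent.

## Layout

| module | contents |
| --- | --- |
| `consnet.trees` | tree/split model, Newick I/O, compatibility, RF distance, SPR, first-degree incompatibility |
| `consnet.weights` | overall cluster weights (three modes) and ranking |
| `consnet.consensus` | the four consensus constructions |
| `consnet.networks` | reticulation admission, direction finding, network assembly |
| `consnet.sliding_window` | MSA I/O, window enumeration, interval-annotated scans |
| `consnet.inference_nj` | distances, neighbor joining, bootstrap supports |
| `consnet.simulate` | benchmark generators and TP/FP scoring |
| `consnet.cli` | the `consnet` command |
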