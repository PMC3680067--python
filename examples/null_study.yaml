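# Type-I-error study under the null (the putative patient variable P has no
# effect in either sub-model).  Reduce or raise `reps` to trade precision for
# time; `--reps`/`--seed` on the command line override this file.
kind: rejection
reps: 500
seed: 0
alpha: 0.05
strategies: [found_in_either, found_in_both, bonferroni, global]
scenarios:
  - n_cycles: 400
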