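# irescan

Length-independent sequence and structure features for internal ribosome
entry site (IRES) discovery in RNA, with a gradient-boosted classifier and
sliding-window genome scanning.

The package computes:

* **Global kmer features** — overlapping kmer counts for k = 1..4 divided
  by sequence length (4 + 16 + 64 + 256 = 340 features).
* **Local kmer features** — the same vocabulary counted in 20-base windows
  stepping 10 bases from the 5' end (a 173-base sequence gives 16 full
  windows = 5440 features, or 5780 with the optional truncated final
  window). Features are named `<word>_<window start>`, e.g. `U_121`.
* **Triplet features** — joint encoding of the pairing state of three
  adjacent bases (paired/unpaired from a dot-bracket structure) plus the
  central base: 8 x 4 = 32 features, normalized to sum to 1.
* **Q_MFE** — a permutation statistic `n / (N + 1)` comparing a sequence's
  predicted minimum free energy (PMFE) to that of N dinucleotide-preserving
  Euler shuffles; low values indicate more structure than chance. Triplets
  plus Q_MFE form the 33-feature structural vector.
* **Classifier** — gradient-boosted decision trees (scikit-learn backend)
  with XGBoost-style hyperparameter naming, 90/10 train/validation
  splitting, 10-fold cross-validated grid search, rank-based AUC, and
  gain-based feature ranking.
* **Scan** — sliding-window Q_MFE profiles and model-probability profiles
  with threshold calling and BED export.
* **Dataset tools** — filtering/labeling of bicistronic-assay activity
  tables (category whitelist; splicing score > -2.5; promoter activity
  < 0.2; IRES label when activity > 600, all inequalities strict) and a
  seeded synthetic fixture generator emulating that schema.

Folding is a pluggable engine contract. The built-in `baseline` engine is
a deterministic maximum-scoring nested-pairing folder (minimum hairpin
loop 3) suitable for offline work and testing; `external[:command]` wraps
an installed thermodynamic folder such as RNAfold when one is available.
The engine used is recorded in all outputs.

## Test

```sh
python -m pytest tests/
```

## CLI

All commands are deterministic given `--seed` (default 0) and write a
provenance sidecar (`<out>.prov.json`) next to each output.

```sh
# feature matrix (TSV; rows = sequences)
irescan features in.fa --global-kmers --out features.tsv
irescan features in.fa --local-kmers --window 20 --step 10 --partial-final-window

# per-sequence PMFE / Q_MFE
irescan qmfe in.fa --n-shuffles 2000 --engine baseline --seed 1 --out qmfe.tsv

# filter + label an assay table
irescan dataset assay.tsv --out labeled.tsv

# train, predict, scan
irescan train labeled.tsv --features global-kmer --n-rounds 300 --out model.joblib
irescan predict --model model.joblib --fasta in.fa --tsv probs.tsv
irescan scan long.fa --mode model --model model.joblib --threshold 0.1 \
    --out profile.tsv --bed calls.bed
irescan scan long.fa --mode qmfe --window 200 --out qmfe_profile.tsv
```

## Notes

* Published hyperparameter defaults are retained (eta 0.01, max_depth 5,
  min_child_weight 19, subsample 0.8, colsample_bytree 0.65, 1281 rounds);
  the gradient-boosting backend is scikit-learn, so gamma/lambda/alpha are
  recorded in the config but have no direct effect, and min_child_weight
  maps to a minimum leaf size.
* Sequences may be supplied in the DNA alphabet; T is mapped to U. Under
  the default `normalize` policy ambiguity codes are retained but flagged,
  and any kmer/triplet window touching them contributes no counts; the
  `strict` policy rejects them.
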