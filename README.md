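# modmix

Annotation-free module discovery and horizontal integration for
multi-omics abundance data.

## The problem

Untargeted metabolomics, proteomics and transcriptomics experiments
routinely measure thousands of features per sample, many of which lack a
database identity (unidentified metabolite peaks, uncharacterized
transcripts).  Pathway-based integration tools discard those features.
`modmix` instead discovers *data-driven modules* per omics layer — groups
of features that are directly associated with each other — and links the
layers by correlating module summaries, so unidentified features
participate on equal terms with annotated ones.

## The method

Per dataset (features × samples matrix **X**, cleaned and standardized):

1. **Sparse Gaussian graphical model.**  The graphical lasso estimates a
   sparse precision matrix by maximizing

   log det Θ − tr(SΘ) − λ Σ<sub>i≠j</sub> |θ<sub>ij</sub>|

   over positive-definite Θ, with S the empirical correlation matrix and
   the diagonal unpenalized (default λ = 0.25).  Partial correlations
   follow as ρ<sub>ij</sub> = −θ<sub>ij</sub> / √(θ<sub>ii</sub> θ<sub>jj</sub>);
   unlike marginal correlations they encode *direct* associations only.
2. **Topological overlap.**  The unsigned adjacency a<sub>ij</sub> = |ρ<sub>ij</sub>|
   is converted to the topological overlap matrix
   t<sub>ij</sub> = (L<sub>ij</sub> + a<sub>ij</sub>) / (min(k<sub>i</sub>, k<sub>j</sub>) + 1 − a<sub>ij</sub>),
   with L<sub>ij</sub> = Σ<sub>u≠i,j</sub> a<sub>iu</sub> a<sub>uj</sub> and
   k<sub>i</sub> = Σ<sub>u≠i</sub> a<sub>iu</sub>, which scores how much
   network neighbourhood two features share.
3. **Modules.**  1 − TOM is clustered with average linkage and the
   dendrogram is cut with the dynamic hybrid method (static height cut,
   branch-shape criteria, PAM-like reassignment of leftovers); unassigned
   features get label 0.
4. **Eigenfeatures.**  Each module is summarized by the first principal
   component of its members across samples (mean 0 / SD 1, sign fixed
   against the module mean profile), with per-feature loadings and module
   memberships (kME).

Across datasets, every pair of eigenfeatures is Spearman-correlated;
Benjamini–Hochberg q-values over all pairs, the top-K pairs, and a module
network (GraphML) are reported.  Eigenfeatures are also tested against
sample groupings (Welch t for two groups, Kruskal–Wallis beyond).

## Worked example

The built-in generator plants known module structure: here two omics
layers sharing 100 samples, six rank-1 modules of 30 features each
(within-module correlation 0.6), 40 background features, and two
cross-layer latent couplings of strength 0.9.

```python
from modmix import (SimConfig, generate_multiomics, modules_from_matrix,
                    eigenfeatures_for_all, integrate_all, top_correlations,
                    evaluate_recovery)
from modmix.preprocess import standardize

matrices, metadata, truth = generate_multiomics(SimConfig(seed=42))
eigensets = []
for m in matrices:
    z = standardize(m)
    assignment, dendrogram, tom, partials = modules_from_matrix(z)
    stats = evaluate_recovery(assignment, truth, m.omics_name)
    print(f"{m.omics_name}: {stats['n_modules']} modules, "
          f"mean size {stats['mean_size']:.1f}, ARI {stats['ari']:.2f}")
    eigensets.append(eigenfeatures_for_all(z, assignment))

edges = integrate_all(eigensets)
for e in top_correlations(edges, 2):
    print(f"{e.dataset_a} M{e.module_a} -- {e.dataset_b} M{e.module_b}: "
          f"rho={e.rho:.3f}, q={e.q_value:.2e}")
```

Output:

```
omics1: 6 modules, mean size 30.7, ARI 1.00
omics2: 6 modules, mean size 30.2, ARI 1.00
omics1 M2 -- omics2 M3: rho=0.838, q=5.32e-26
omics1 M3 -- omics2 M1: rho=0.826, q=6.81e-25
```

Both layers recover the planted partition exactly (adjusted Rand index
1.0), and the two strongest cross-layer edges are precisely the two
planted couplings: a coupling of strength 0.9 between latents appears as
an eigenfeature Spearman correlation of ~0.83–0.84 once module noise is
folded in.

## Command line

```bash
modmix simulate --outdir fixture --seed 42      # write a synthetic fixture
modmix run --config run.yaml                    # full pipeline
modmix scan-lambda data.csv --lambdas 0.1,0.25,0.4
```

`run.yaml` lists the datasets, metadata path, output directory and any
stage options (see `modmix run --help`); each stage is also available as
its own subcommand (`preprocess`, `modules`, `integrate`, `phenotype`)
operating on intermediate files.

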