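# Methods

This note documents the models implemented in `achescreen`, the choices
made where the design was genuinely open, and what the synthetic-data
generators do and do not emulate.

## Thermodynamic conversion

Measured inhibition constants are converted to binding free energies with

    dG = R * T * ln(K),    K in mol/l,    R = 1.987e-3 kcal mol^-1 K^-1,

applied identically to Ki and IC50 (`ki_to_dg`, `ic50_to_dg`; two names so
call sites document which constant they hold).  Unit conversions from nM
and uM use the exact factors 1e-9 and 1e-6.  Temperature is an explicit
parameter everywhere.  The default is **T = 300 K** because the packaged
validation table's experimental column reproduces at 2 d.p. only with
RT ≈ 0.596 kcal/mol; 298 K, the other common convention, changes the
converted values by ~0.7%.  The package does not try to reconcile the two —
it exposes `T` and defaults to the value the packaged table is consistent
with.

## Affinity regression

`affinity_model.train` fits one of three regressor families mapping
molecular descriptor vectors to dG: ordinary linear regression
(`scikit-learn`), random forest (`scikit-learn`), and gradient boosting
(`xgboost`, single-threaded `hist` tree method so results are bit-stable
for a fixed seed).  The split is a seeded random permutation with
`n_train` records in the training set and the remainder held out; the
reported metrics (RMSE, Pearson R, Spearman rho) are computed on the
held-out records only.

Metric uncertainties are the standard deviation of each metric over paired
nonparametric bootstrap resamples (default 1000, seeded).  The bootstrap is
model-agnostic and makes no distributional assumption; it is the package's
choice of uncertainty method for all evaluate()-style comparisons.
Degenerate inputs are handled explicitly: fewer than three pairs is an
error, and zero variance in either vector yields RMSE with the correlations
reported as missing (they are undefined, not zero).

Compound selection (`select_top`) reads "stronger than a threshold" as a
strict inequality (`dg_pred < t`) and breaks top-k ties lexicographically
by compound id, so selections are deterministic and threshold selections
are nested as the threshold loosens.

## Similarity search

Similarity is the Tanimoto coefficient |A∩B|/|A∪B| on fixed-length
fingerprint bitsets — the standard 2-D chemical similarity measure and the
one used by the large public compound databases this package's local
`Library` stands in for.  Two conventions:

* two all-zero fingerprints score 1.0 (they are identical objects; 0/0 is
  resolved in favour of identity);
* `neighbor_search` excludes the seeds themselves from its hit set, because
  a search round is scored on *newly identified* compounds.

The default similarity cutoff is 0.9, the customary default threshold for
2-D similarity queries against public databases; it is a config value, not
a constant.  The fingerprint source is pluggable: `fingerprint_from_smiles`
derives Morgan bits via RDKit for real chemistry, while the synthetic
generator produces structured bitsets with provable similarity floors, so
the search engine itself is testable without any chemistry toolkit.

## Enrichment campaigns

A campaign alternates prediction and similarity search: round 0 scores the
initial library; each later round seeds a neighbor search with the
strongest predicted binders of the previous round (per-round selection
spec: a dG threshold for round 1, top-k for later rounds, both
configurable), scores the new hits, and summarizes their predicted-dG
distribution by median and quartiles (linear interpolation of order
statistics, the common default).  Rounds are summarized independently —
hit sets are not merged across rounds — and each round's summary excludes
its seeds.  Successful enrichment shows as non-increasing round medians.

### The planted benchmark

`make_screening_benchmark` builds the world in which enrichment is
measurable.  Scaffold mean affinities scatter around −7.5 kcal/mol
(sd ≈ 0.75); one scaffold is pinned at −11 kcal/mol (the potent target) and
one at −10.3 kcal/mol (an intermediate tier).  The intermediate tier is a
deliberate design element, not decoration: in a *closed* library a single
potent scaffold cannot produce monotone medians over two rounds, because
the second round's seeds are the first round's best hits and seeds are
excluded from their own round — round 2 would return the same potent
cluster minus its nine best members, a strictly worse median.  With a
potency gradient, round 1 mixes the potent and intermediate tiers while
round 2's top-k seeds come from the potent tier alone, so the final
distribution concentrates on the strongest binders, mirroring the
round-over-round shift the procedure is designed to produce.  Default
scale: 40 scaffolds x 50 compounds (2000-compound search library), a
200-compound initial subset (5 per scaffold), label noise 0.3 kcal/mol,
descriptor jitter 0.25 per dimension.  The accompanying training library
(1426 compounds, the scale of a curated inhibition-constant collection)
shares the benchmark's descriptor-to-dG coefficients but none of its
records.

## Linear interaction energy

The binding free energy estimator is

    dG_LIE = alpha * (<V_vdw>_bound - <V_vdw>_unbound)
           + beta  * (<V_cou>_bound - <V_cou>_unbound) + gamma

with alpha = 0.288, beta = −0.049, gamma = −5.88 kcal/mol, empirical
coefficients transferred from a receptor with a similarly shallow binding
cleft.  They are data, not constants: `LIEParameters` carries them and any
other parameterization can be supplied.

Traces are read from GROMACS-dialect XVG files ('#'/'@' metadata, then
whitespace-separated time + energy columns; vdW/Coulomb columns identified
from the `s0/s1` legends or an explicit column map; kJ/mol converted to
kcal/mol by the exact factor 4.184 at I/O — internally everything is
kcal/mol).  The first 20% of each trace's time span is discarded as
equilibration by default (`equil_fraction`, configurable; typical MD
practice, as production trajectories begin before full relaxation).

Replica aggregation computes one dG per replica from that replica's bound
and unbound means, then reports mean ± SEM across replicas, with SEM =
sample sd (n−1 denominator) / sqrt(n).  This per-replica-first convention
matches how replica-averaged LIE results are customarily quoted.  A single
replica reports SEM 0 with an explicit flag; a single unbound trace can be
shared across bound replicas with `allow_shared_unbound`; a pooled mode
(concatenating production frames per state) is available but not the
default.  Replica count is a config, not a constant — published workflows
variously use two or four.

**Calibration caveat.**  With n replicas, (dG − truth)/SEM is
Student-t-distributed with n−1 degrees of freedom, so with the common
n = 4 the interval dG ± 3·SEM covers the true value ~94.2% of the time,
not the ~99.7% a normal intuition suggests; ±3·SEM only reaches 99%
coverage from about n = 16 replicas.  The test suite checks the empirical
coverage against the t-distribution prediction; users quoting ±SEM from
few replicas should widen intervals with the appropriate t quantile.

## Contact analysis

Hydrogen bonds use a purely geometric criterion at the receptor–ligand
interface: donor–acceptor distance ≤ 3.5 Å and acceptor–hydrogen–donor
angle, measured at the hydrogen, ≥ 135°.  The angle-at-hydrogen convention
is applied literally (some trajectory tools instead gate on the
hydrogen–donor–acceptor angle ≤ 30°; the two conventions agree on strong,
near-linear bonds and differ at the margins).  Donors are N/O/S atoms with
at least one covalently bound hydrogen; acceptors are N/O (S behind a
flag).  With no topology available, covalent bonds are inferred by
distance < 1.2 x the sum of covalent radii; each hydrogen is assigned to
its nearest donor-capable heavy atom.

Side-chain (heavy-atom) contacts count a receptor residue when any of its
non-hydrogen atoms is within 4.5 Å of any ligand non-hydrogen atom.  The
criterion deliberately includes backbone heavy atoms (a strict
side-chain-only mode exists behind a flag) since the distance definition is
stated over non-hydrogen atoms generally.

Contact probabilities over a trajectory are fractions of frames with at
least one qualifying contact per residue.  Trajectories are multi-model
PDB files (model order = frame order), read via MDAnalysis; elements come
from the PDB element column, falling back to the first letter of the atom
name.

RMSD uses least-squares rigid-body superposition (Kabsch, via
`scipy.spatial.transform.Rotation.align_vectors`) on a fit selection, then
measures over a measurement selection; an unfitted mode is available.  The
test suite cross-checks the fitted minimum against an independent zooming
rotation-grid search.

## Synthetic data: what it does and does not show

The generators reproduce the *statistical contracts* of the real inputs,
nothing more:

* **Libraries** have exact scaffold block-structure in fingerprint space
  (within-scaffold Tanimoto provably ≥ a floor via an analytic flip
  budget k ≤ w(1−f)/(2(1+f)); cross-scaffold similarity exactly 0) and
  labels exactly linear in descriptors plus Gaussian noise.  Real
  fingerprint spaces have soft cluster boundaries, correlated bits and
  non-linear structure–activity relationships; passing tests show the
  search/selection/regression machinery is correct, not that any given
  chemistry will enrich.
* **Energy traces** are stationary AR(1) processes with prescribed means,
  marginal sd (default 3 kcal/mol) and autocorrelation time (default
  10 ps at 2 ps spacing, 25 000 frames ≈ a 50 ns production run).  Real
  interaction energies have multi-scale correlations and occasional slow
  conformational drifts; AR(1) captures the first-order effect that
  makes naive SEMs optimistic, which is the property the calibration test
  exercises.  Default true means are chosen to give an analytic
  dG_LIE = −11.02 kcal/mol, a mid-table value for this receptor class.
* **Trajectories** plant contacts by exact frame counts (not Bernoulli
  draws), so probability recovery is an equality check.  Because any
  qualifying hydrogen bond necessarily brings a ligand heavy atom within
  the heavy-atom cutoff of the donor residue, HB frames are planted as a
  subset of SC frames and the generator rejects plans with
  hb_fraction > sc_fraction.  The geometry is schematic (one donor, one
  probe atom pair per residue, residues 30 Å apart); it validates the
  detection geometry, not receptor realism.

All generators are pure functions of their seed.

## Problem sizes

Default experiment sizes keep every check fast while leaving the
statistics meaningful: 100 seeded worlds x 4 replicas x 25 000 frames for
LIE calibration; 20 worlds x 2000-compound libraries for the enrichment
property; 100 frames x 10 residues for contact recovery; 3-atom toys for
the RMSD oracle.  The full acceptance script completes in a few seconds on
one CPU.

## Known limitations

* No docking, no MD engine, no force-field handling: structures and energy
  traces are inputs.
* SMILES are passed through, not canonicalized; deduplication is by
  compound id only.
* The LIE coefficients are taken as given; no refitting machinery is
  provided.
* The 7D9O row of the packaged validation table is internally inconsistent
  (rounded 3 nM IC50 vs tabulated −11.77 kcal/mol, which implies ~2.66 nM);
  the fixture stores the values verbatim and flags the row rather than
  silently correcting either number.
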