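# Methods

This note documents the models, parameter choices, and numerical decisions
behind `milkpep`, and what the synthetic-data-based tests do and do not
demonstrate about real data.

## Proteolysis model

Digestion is the idealised rule-based model used by proteolysis-simulation
databases: an enzyme is a set of cleavage rules, a rule names the residues
cut on their carboxyl side (P1) and the residues that veto the cut when
they follow the bond (P1'). Every bond matched by at least one rule of at
least one selected enzyme is cut — the combined action of several enzymes
is the union of their sites, applied in a single pass — and no missed
cleavages occur. This is an upper bound on fragmentation: real digestion
is kinetically incomplete, so observed hydrolysates contain longer
fragments and fewer short peptides than the simulation predicts.

Default specificities (data, in `data/enzyme_rules.yaml`, overridable from
a user YAML file):

| enzyme            | EC        | cuts after | blocked by following |
|-------------------|-----------|------------|----------------------|
| pepsin (pH > 2)   | 3.4.23.1  | F, L       | —                    |
| trypsin           | 3.4.21.4  | K, R       | P                    |
| chymotrypsin      | 3.4.21.1  | F, Y, W    | P                    |

Trypsin and chymotrypsin follow the conventional ExPASy-style rules. The
exact rule set behind the "pepsin (pH > 2)" model of the simulation
databases is not published; F/L with no proline block is the common
minimal convention and is the single most uncertain default here — it is
deliberately configuration, not code. Coordinates are 1-based and
inclusive; the C-terminal residue has no following bond and therefore
never creates a site.

## Release-potential statistics

For a protein of N residues, an activity class, and a knowledge table of
(peptide, activity, optional IC50 [µM]) records:

* `a` — occurrences of active peptides as substrings, with multiplicity
  (overlaps and repeats counted); `A = a/N`.
* `d` — active peptides among the digestion fragments, counted per
  fragment instance; `A_E = d/N`. Fragments of length 1 never match: a
  free amino acid is not a peptide.
* `B = (Σ 1/IC50_i over occurrences with known IC50)/N`, `B_E` the same
  over released instances; units µM⁻¹. Records without an IC50 count in
  `a`/`d` but are excluded from `B`/`B_E`, which therefore understate
  activity when the table is sparsely quantified.
* `W = A_E/A` and `V = B_E/B` are reported as undefined (not zero) when
  the denominator is zero, since a 0/0 ratio carries no information.

Instance counting (rather than distinct-sequence counting) is used in both
the frequency and the activity sums; it keeps `A·N` and `A_E·N` exact
integers and treats a peptide occurring twice as twice the release
potential. The alternative distinct-sequence convention can be obtained by
deduplicating the occurrence list, but is not exposed as a switch because
nothing downstream needs it. Report tables round to 4 decimals for display
only; full precision is kept internally.

The implementation is verified against a brute-force oracle that
enumerates every substring and every fragment on seeded synthetic
instances (see below), not against published per-protein tables: those
depend on the contents of a peptide-activity database snapshot that is not
redistributable, so exact reproduction is out of scope by design.

## Mass and fragment-ion arithmetic

Monoisotopic residue masses are the standard elemental values rounded at
the 5th decimal; water = 18.010565 Da, proton = 1.0072765 Da (proton, not
hydrogen atom — the electron mass shows at the 4th decimal). Neutral mass
is Σ residues + water; [M+H]+ adds the proton. Singly charged fragment
ions: `b = Σ prefix + proton`, `a = b − CO`, `c = b + NH3`,
`y = Σ suffix + water + proton`, `x = y + CO − H2`, `z = y − NH2`;
neutral losses (H2O 18.010565, NH3 17.026549, HCOOH 46.005480) subtract
the molecule mass. Theoretical reference spectra for di- to pentapeptides
contain all six series, all three losses, and the precursor, deduplicated
at 1e-4 Da.

The packaged identification table's printed m/z values agree with this
constant set within 0.0005 Da on all 36 rows; a handful differ in the last
printed digit from any single consistent constant set (e.g. SG printed
163.0714 vs computed 163.0713), so comparisons against printed values use
a 0.0005 Da tolerance rather than exact 4-decimal equality. I and L are
isobaric; all mass-based matching therefore reports isomer sets.

## Identification

A candidate is scored by the fraction of its theoretical ions found in the
observed peak list within a fragment tolerance (default 0.005 Da), after a
precursor filter (default 0.01 Da) — tolerances of a Q-ToF instrument at
the printed 4-decimal accuracy. Intensities are ignored: small-peptide
identification rests on the presence of distinctive ions, not on intensity
models. The result is the isomer set of the top scorer: all candidates
tying the best score plus all candidates with the same collapsed residue
composition (I = L), because composition-identical dipeptide pairs such as
PL/IP share the precursor and co-elute. Retention time is never used to
break isomer sets. An optional minimum matched-ion count rejects sparse
matches on decoy-like spectra.

The autolysis screen partitions identified peptides by whether they occur
as substrings in the sequences of the digestive proteases themselves
(trypsin P00761, pepsin A P00791, chymotrypsinogen A P00766); a peptide
present in an enzyme sequence cannot be attributed to the food protein
with confidence. The enzyme FASTA is fetched once by the user and is not
redistributed with the package.

## Bioassays and IC50

The five percentage formulas are ratios of role-labelled absorbances (see
the module docstring); each is scale-invariant under a common rescaling of
the reader. IC50s are fitted on the log10 concentration axis with the
fixed-asymptote (0/100), variable-slope logistic — the "normalized
response" inhibition model. A free-asymptote variant is intentionally not
the default: responses entering the fit are already percentages of a
defined full scale.

Numerical choices: deterministic initialisation (log10 IC50 at the tested
concentration whose response is nearest 50 %, Hill slope 1), which is
robust on any monotone series; asymptotic standard errors from the scaled
least-squares covariance, mapped to the IC50 scale by the delta method
(SE = ln10 · IC50 · SE_log). A fit is flagged not-converged when the
optimiser fails, the Hill slope is non-positive (responses falling with
dose contradict an inhibition curve), or the estimate lands more than 10×
outside the tested range — flagged, never silently returned.

Plate data are fitted at replicate level: each replicate percentage is an
individual point rather than being averaged per concentration first. For
a balanced design the point estimate is identical, but the residual
degrees of freedom stay honest — with 5 averaged points and 2 parameters
(3 residual dof) a ±2·SE interval covers only ~86 % (the t(3) prediction),
whereas replicate-level fitting of a duplicate 5-concentration design
reaches the nominal ~92–95 %.

## Synthetic data and what the tests show

All generators are pure functions of (config, seed), each drawing from its
own stream derived from `(seed, stream id)`. Defaults encode the study
conditions: 8 proteins; an activity table of 59 peptides (52 di-, 7 tri-)
with activity classes weighted 27:27:5 toward ACE and DPP-IV inhibition,
IC50s log-uniform on 1–1000 µM and present for half the records;
dose–response series of 5 concentrations log-spaced one decade either side
of the IC50, duplicate readings, Gaussian noise of 3 percentage points;
spectra with 0.002 Da m/z jitter, 10 % peak dropout, and 10 uniform decoy
peaks on [50 Da, precursor].

The generators reproduce the *statistical structure* each stage assumes —
i.i.d. residues, exactly matching substrings, curves with known truth,
peaks with symmetric noise. They do not emulate real biology or
instrumentation: no residue autocorrelation or domain structure, no
incomplete hydrolysis, no intensity structure, retention behaviour, or
systematic mass calibration error. Passing tests therefore certify the
correctness of the computations and the statistical behaviour of the
estimators under the stated noise model, not field performance on real
digests.

Problem sizes used by the verification suite (chosen to make the checks
statistically meaningful at interactive runtimes): digestion oracle
equivalence on 1,000 random sequences of length 2–200; release-statistics
oracle equivalence on 200 seeded (protein, table) instances; fragment-ion
identities on 500 random peptides; 500 seeded plate simulations for the
IC50 estimator (median |relative error| < 10 %, ±2·SE coverage ≥ 90 %);
200 seeded jittered spectra with 50 decoy candidates for identification
(≥ 95 % isomer-set recovery).

## Known limitations

* The pepsin (pH > 2) rule set is a convention, not a published
  specification; release statistics under pepsin-containing digests inherit
  that uncertainty.
* Exhaustive cleavage overestimates fragmentation relative to real
  (incomplete) digestion; the release parameters are potentials, not
  predictions of hydrolysate composition.
* `B`/`B_E` depend on which table records carry IC50s and understate
  activity for sparsely quantified tables.
* Only singly charged ions and unmodified residues are modelled (no
  isotope envelopes, no methionine oxidation), matching the small-peptide,
  low-charge scope.
* In the packaged identification table, the per-sample presence totals
  implied by the rows are (2, 30, 4, 30, 1, 27); `summarize` reports what
  the rows imply.
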