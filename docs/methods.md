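# Methods

## The problem

Untargeted LC-MS/MS of a microbial extract yields hundreds to thousands
of MS2 spectra, most of them irrelevant to any one discovery campaign.
When a compound family shares a conserved substructure — a *building
block* — that substructure produces the same characteristic (diagnostic)
product ion in every member's MS2 spectrum, because the fragment
carrying it does not change while the rest of the molecule does.
Filtering the dataset for that one ion pulls the whole family out of the
noise before any isolation work begins; combining the filter with
spectral-similarity networking then shows how the recovered spectra
relate to one another.

The package implements this workflow end to end: exact-mass and formula
arithmetic, MGF ingestion, diagnostic-ion / neutral-loss filtering,
fragmentation-cascade annotation, modified-cosine networking, and an
in-silico fragmentation simulator that provides labeled ground truth.

## Formula and mass arithmetic

Monoisotopic masses use the IUPAC values (C 12 exactly, H 1.0078250319,
N 14.0030740, O 15.9949146, S 31.9720707, P 30.9737615, plus Si and the
halogens). `[M+H]+` is computed by adding the hydrogen-atom mass
(1.00783 Da) to the neutral monoisotopic mass — the convention under
which published HR-ESI-MS "calculated" values are tabulated. The
physically strict alternative (bare proton, 1.007276 Da, accounting for
the lost electron) is available behind `strict_proton=True`; the two
differ by 0.55 mDa, visible at the fourth decimal only in edge cases.
Reported m/z values are rounded to 4 decimals; all internal arithmetic
is full precision.

RDBE (ring-plus-double-bond equivalents) uses standard valences
(C/Si 4, N/P 3, O/S 2, H/halogen 1):
`RDBE = 1 + Σ count·(valence − 2)/2`. It is integral for neutral
formulas; no special handling of radicals or charged species is
attempted.

Worked anchor values used throughout the tests: the pyranopyrrole
monomer C15H23NO5 gives [M+H]+ 298.1654; its symmetric [2+2] dimer
C30H46N2O10 gives [M+H]+ 595.3231 with RDBE 9.

## Neutral-loss library

The built-in library holds H2O (18.0106), CH2O (30.0106), CO (27.9949),
C5H10 (70.0783), CH3OH (32.0262) and NH3 (17.0265). The first four are
the losses that dominate pyranopyrrole fragmentation; methanol and
ammonia are conventional additions. Users can replace the library with
a TSV (`label`, `formula`, optional `mass`); masses are always
recomputed from the formula, and a stated mass deviating by more than
1e-3 Da is rejected rather than silently trusted. Loss matching picks
the entry with the smallest absolute deviation, breaking ties toward the
smaller loss mass and then the lexicographically smaller label — in
practice the library is sparse enough that ties never occur.

## Filtering

A `DiagnosticQuery` carries target product-ion m/z values and/or
precursor-relative neutral-loss masses, an m/z tolerance (default
0.02 Da, absolute; a ppm mode exists but is off by default), and a
minimum peak area (default 1.0E4). "Area" here is the MS2 fragment
peak's intensity as recorded in the MGF — no MS1 feature detection is
performed, so no chromatographic areas exist at this stage; the
threshold is a plain parameter, so a pipeline that exports MS1-derived
areas into its MGF works unchanged.

Per (spectrum, target) pair, the most intense qualifying peak is
reported (tie: smallest deviation, then lowest m/z); hits are ranked by
area descending. Both tolerance and threshold are monotone by
construction: widening the tolerance or lowering the threshold can only
add hits — the property suite checks this on random spectra.

## Cascade annotation

`annotate_cascade` walks greedily down from the precursor: at each node
it takes the highest-m/z peak (above a relative-intensity floor,
default 1% of the base peak) whose mass difference from the current node
matches a library loss within tolerance, and stops when nothing matches.
The walk is strictly linear; branched fragmentation trees are a
non-goal. Greedy highest-m/z-first is the right bias for sequential
small-molecule losses, where each daughter ion sits just below its
parent.

The retro-[2+2] signature of a symmetric dimer — precursor splitting
into two identical halves — is detected separately: a fragment f is
flagged when the neutral complement `precursor_mz − f` equals the
fragment's own neutral mass `f − 1.00783` within tolerance. This is
deliberately not folded into the loss library (the "loss" is half the
molecule and varies per compound).

## Networking

The modified cosine follows molecular-networking practice: square-root
intensity scaling, unit-norm vectors, candidate peak pairs matched
either directly or offset by the precursor mass difference
(fragment tolerance 0.02 Da), and a greedy one-to-one assignment by
descending weight product (tie: smaller m/z difference). Greedy rather
than optimal assignment matches common practice and is guarded by an
exact Hungarian-algorithm oracle in the test suite; on 500 random
small instances the two agree to 1e-9, and the implementation also
agrees with matchms' modified cosine at matching parameters. Peaks
within 17 Da of the precursor are removed before scoring (they carry no
structural information and inflate similarity); `precursor_window=None`
disables this.

Network assembly keeps edges with score ≥ 0.7 and ≥ 4 matched peaks,
then applies per-node top-k retention (k = 10: an edge survives only if
it ranks in the top k of both endpoints), then splits components larger
than 100 nodes by repeatedly deleting the weakest edge (ties: larger
precursor delta, then lexicographic ids — fully deterministic).
These defaults are the de-facto molecular-networking standard; every one
is a parameter. Component ids are assigned by each component's smallest
member id, so outputs are stable across runs.

`consensus_diagnostic` automates diagnostic-ion selection: product ions
from a candidate family are single-linkage clustered within the m/z
tolerance, and clusters are ranked by the number of distinct supporting
spectra, then by total intensity. The conserved building-block ion of a
genuine family tops this ranking with full support.

## The simulator

`fragmentation_sim` emulates the data situation the method targets, not
the physics of fragmentation. The default scaffold is the
pyranopyrrole monomer: protonated parent 298.1654 losing H2O, CH2O and
C5H10 in sequence down to the characteristic ion at m/z 180.0671, the
conserved pyranopyrrole fragment.

Design choices and what they encode:

- **The diagnostic ion is never shifted.** Family members are generated
  at precursor shifts of 0, +O (15.9949) and +H2O (18.0106), modelling
  hydroxylation/hydration analog series; the cascade ladder shifts with
  the precursor, while the diagnostic ion and two secondary fragments of
  the same unit (153.0546, 135.0441) stay fixed. This is the method's
  core premise — the building block is the invariant part.
- **Secondary conserved fragments.** Real building blocks yield more
  than one stable ion; the two secondaries give family spectra five
  shared peaks, comfortably above the network's min-matched-peaks
  default of 4. Their offsets from the diagnostic ion deliberately match
  no library loss, so cascade annotation terminates at the right node.
- **Ladder terminal vs measured diagnostic.** The arithmetic ladder
  terminal (180.0660) and the measured diagnostic value (180.0671)
  differ by ~1 mDa, as calculated and observed values do on a real
  instrument; the generator emits the measured value in place of the
  terminal when the two agree within 0.05 Da, otherwise both.
- **The hydrated analog's extra water.** For the +H2O analog the ladder
  terminal sits exactly one water above the diagnostic ion, so cascade
  annotation appends one extra H2O step. That is chemically correct (the
  analog sheds its extra water) and the tests assert the scaffold
  sequence as a prefix, exact for the unshifted member.
- **Noise is sub-threshold by construction** (intensities in
  [1e3, 9.5e3), strictly below the 1.0E4 area default), so the area
  threshold is the discriminator being exercised; real fragments are
  floored at 1.2e4 after intensity jitter (CV 0.2). Noise m/z avoids
  ±0.05 Da windows around the diagnostic ions and the retro-[2+2]
  half-mass point so the labeled contracts are exact.
- **Decoys** draw 8–15 random peaks with an exclusion guard of 2× the
  m/z tolerance around every scaffold diagnostic ion: a decoy can never
  produce a hit, which makes precision/recall against generator labels
  exact rather than probabilistic.
- **m/z jitter** is Gaussian with σ = 0.005 Da by default (Q-TOF-like at
  this mass range); a constant-Da rather than ppm-proportional model is
  adequate over m/z 100–600. At σ = 0.005 the filter's recall contract
  holds (tolerance 0.02 = 4σ); at σ comparable to the tolerance it would
  not, and no contract is claimed there.
- All randomness flows through one `numpy` Generator; a fixed
  `SimConfig` yields byte-identical MGF output.

What the simulator does **not** model: bond-energy-driven fragment
abundances, rearrangement chemistry beyond a labelled −H2O channel,
isotope envelopes, chimeric spectra, or realistic retention-time
structure (RT is a uniform draw). Passing tests therefore demonstrate
the pipeline's correctness and its discrimination behavior under the
stated noise model — not performance on vendor data, where isobaric
interferences and co-isolation can produce diagnostic-ion false
positives that this generator excludes by construction.

## Problem sizes

The shipped tests and the acceptance script run on deliberately small
instances — a 17-spectrum dataset (6 family + 1 dimer + 10 decoys),
500-case oracle comparisons, 200-spectrum property sweeps — chosen so
the full suite completes in seconds while still exercising every code
path; all generators scale to larger runs via `SimConfig`.

## Known limitations

- MGF is the only input format; mzML/mzXML and vendor formats are out of
  scope (export to MGF first).
- Only singly protonated, monoisotopic species: no charge states,
  adducts, or isotopologue arithmetic.
- Cascade annotation is linear and greedy; it will follow the single
  most plausible chain and never backtrack.
- Spectral-library annotation (matching against public MS2 libraries) is
  intentionally absent; the network and flags organize spectra, humans
  or other tools name them.
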