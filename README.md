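# bbmn — building-block molecular networking for tandem MS

Natural-product discovery from a microbial extract usually starts with
one known compound and the suspicion that its structural relatives are
hiding in the same LC-MS/MS run. When a compound family shares a
conserved substructure — a *building block* — every member's MS² (MS/MS)
spectrum contains the same characteristic **diagnostic product ion**,
because the fragment carrying that substructure is invariant while the
rest of the molecule changes. `bbmn` turns that observation into a
pipeline: filter the MS² dataset for the diagnostic ion (or a
characteristic neutral loss), annotate each hit's fragmentation cascade,
and assemble a molecular network in which the building-block-bearing
spectra are flagged for follow-up isolation.

The package is aimed at mass spectrometrists and natural-product
chemists working with centroided MS² data in MGF format.

## What it computes

**Exact-mass arithmetic.** Hill-notation formula parsing, monoisotopic
masses, `[M+H]⁺ = M + 1.00783` (hydrogen-atom convention, matching
published HR-ESI-MS tables), and RDBE
(`C + Si − (H + halogens)/2 + (N + P)/2 + 1`).

**Diagnostic-ion filtering.** A spectrum is a hit for target m/z *t*
when it has a peak *p* with `|m/z(p) − t| ≤ 0.02 Da` and intensity
(peak area) ≥ 1.0E4; hits are ranked by area. Neutral-loss queries work
the same way on `precursor − fragment` differences.

**Cascade annotation.** A greedy walk down from the precursor assigns
each mass difference to a neutral-loss library entry (built-in: H₂O,
CH₂O, CO, C₅H₁₀, CH₃OH, NH₃; user-replaceable). A separate detector
flags the retro-[2+2] signature of symmetric dimers — a fragment whose
neutral complement equals its own neutral mass.

**Networking.** The modified cosine between spectra *a*, *b*:
square-root-scaled, unit-norm peak vectors; peak pairs match directly
(`|m/zₐ − m/z_b| ≤ 0.02`) or shifted by the precursor difference;
greedy one-to-one assignment; score = Σ matched weight products ∈ [0,1].
Edges require score ≥ 0.7 and ≥ 4 matched peaks, survive per-node top-10
filtering, and components are capped at 100 nodes. A consensus step
clusters product ions across a candidate family and ranks them by
supporting-spectrum count — automating diagnostic-ion selection.

**Simulation.** A labeled generator emits a building-block family
(default: the pyranopyrrole scaffold, parent m/z 298.1654 →
−H₂O → −CH₂O → −C₅H₁₀ → diagnostic ion 180.0671, with hydroxylated and
hydrated analogs), a retro-[2+2] dimer at m/z 595.3231, guarded decoys,
and sub-threshold noise — so every claim the package makes is testable
without instrument data.

## Worked example

```
$ bbmn mass C30H46N2O10
formula        C30H46N2O10
monoisotopic   594.3152
[M+H]+         595.3231
RDBE           9
```

The dimer formula C₃₀H₄₆N₂O₁₀ has calculated [M+H]⁺ 595.3231 with nine
degrees of unsaturation — twice the C₁₅H₂₃NO₅ monomer (calculated
[M+H]⁺ 298.1654).

```
$ bbmn simulate --seed 7 --out-mgf run.mgf --out-labels labels.tsv
$ bbmn filter run.mgf --target 180.0671 --hits-out hits.tsv --mgf-out filtered.mgf
7 hits across 7 spectra
$ head -4 hits.tsv
spectrum_id  precursor_mz  target_mz  observed_mz  deviation  area      rank
family_05    314.1604      180.0671   180.0733     0.0062     128834.1  1
family_06    316.1760      180.0671   180.0583     -0.0088    114698.5  2
family_04    298.1654      180.0671   180.0626     -0.0045    103281.1  3
```

The simulated run holds 17 spectra (6 family members, 1 dimer, 10
decoys). Filtering on the diagnostic ion at m/z 180.0671 recovers
exactly the 7 building-block spectra — every family analog and the
dimer, no decoy — each hit reporting the observed ion, its deviation
from the target (all within the 0.02 Da tolerance) and its area.

```
$ bbmn network run.mgf --target 180.0671 --graphml net.graphml --nodes-out nodes.tsv
17 nodes, 15 edges, 12 components, 7 building-block nodes
```

The network connects all six family members into a single component
(the dimer and each decoy stay isolated at the 0.7 score threshold),
and the 7 diagnostic-ion hits carry `building_block = true` in the
GraphML/TSV output, ready for Cytoscape.

```
$ bbmn annotate run.mgf --out cascades.tsv
```

annotates each spectrum's loss cascade; an unshifted family member
reads `H2O>CH2O>C5H10` with terminal m/z ≈ 180.07.

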