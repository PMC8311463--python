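# Methods

## Mass model

All arithmetic is monoisotopic. Residue masses come from
`pyteomics.mass.std_aa_mass`, restricted to the 20 canonical letters;
non-canonical codes (B, Z, X, U, O) are rejected rather than approximated.
Constants: water 18.010565 Da, proton 1.007276 Da, hydrogen atom
1.007825 Da, S-carbamidomethyl 57.021464 Da. Protonation uses the proton
mass; disulfide reduction uses the H-atom mass — the 0.0005 Da difference
is below every tolerance in the pipeline but kept physically correct.

A linear chain carries one water; head-to-tail cyclization removes it.
Each disulfide removes two H atoms; carbamidomethylation adds 57.021464 Da
per cysteine on the reduced form, hence +58.029289 Da per cysteine
relative to the native disulfide form and +348.1757 Da for the six-Cys
scaffold. Ring opening (one hydrolysis) adds one water. Average masses
and isotope envelopes are out of scope: the screening context is MALDI
with singly protonated monoisotopic signals, and charge states above 2
are not supported.

The 280 nm molar absorption coefficient is the standard composition rule
1490·#Tyr + 5500·#Trp + 125·#cystine.

## Derivatization screening

`match_series` chains each native peak through the reduced (+n·1.007825),
alkylated (+n·57.021464 from the reduced anchor) and linearized
(+18.010565) lists. Two tolerance modes exist because they answer
different questions: `ppm` reflects instrument accuracy (default
±25 ppm), while `dalton` (0.2 Da) is needed when peak lists are rounded
to one decimal — the published 18-row table carries step deviations up to
0.17 Da (~50 ppm), so it validates 18/18 in Dalton mode while strict
25 ppm mode passes only 10/18. Both interpretations of the tolerance
(applied per step, anchored on the previous observed peak, or anchored on
the native peak) are exposed via `chaining`; the default
`from_previous_observed` keeps the table's deviations smaller.

Cysteine-count inference searches n = 1..10 (even and odd: other
cystine-rich families differ from cyclotides) and, per native peak, keeps
the n minimizing the total absolute deviation. Injectivity is enforced
globally: no companion peak is claimed by two series; conflicts resolve
by smallest total deviation, then lowest native m/z, and a native whose
best chain is blocked falls back to its next-best n. Classification:
`six_cys_cyclic` requires n = 6 *and* an observed ring-opened product;
n = 6 without it is `incomplete`; other n are `cys_rich_other`.

The "single conserved Glu" logic is also available as an optional flag:
pairs of unclaimed linearized-list peaks whose neutral masses reassemble
the alkylated peptide plus two waters indicate internal GluC sites and
mark the series as suspect.

## Cyclic digestion

Coordinates are 0-based modulo the parent length; the written sequence
starts at the residue after the native ligation site (reports add 1-based
positions). A cyclic parent with k sites yields k complete fragments
(site successor to next site, wrapping), partial products with up to
`max_missed` internal sites (default 2 — the value needed to produce the
full-length tryptic partial of a 3-site parent), and one full-length
single-cut linear form per site, flagged and exempt from the
missed-cleavage cap because it is the MS/MS precursor species. Every
fragment is priced as a linear peptide (one water per cut), so the k
complete fragments sum to the parent mass + k waters — a tested
invariant, along with rotation invariance of the fragment multiset.

Enzyme rules: GluC after E; trypsin after K/R blocked by following Pro
(standard rule; the alca sequences contain no KP/RP so the published
tables are insensitive to it); chymotrypsin after F/Y/W/L/M with
explicitly no Ile cleavage, plus a strict F/Y/W variant. Fragments of
oxidized parents are priced as free thiols since a fragment's disulfide
pairing is undefined.

## MS/MS annotation

Only singly charged b/y ions are modeled (MALDI post-source decay), with
optional −17.026549 (NH3) and −18.010565 (H2O) satellites. b_i is the
i-residue prefix plus a proton; y_i the i-residue suffix plus water and a
proton; the complementarity identity mz(b_i) + mz(y_{n−i}) = M + 2·1.007276
is tested exhaustively. Matching is greedy by absolute error with at most
one peak per (series, index) across loss states. A residue is supported
when a matched ion verifies the bond boundary on either side of it; the
ladder termini count as verified once any ion matches (the precursor mass
is known), so a complete single-series ladder reaches coverage 1.0 — the
published criterion — while an empty spectrum scores 0. The default
matching tolerance is 0.3 Da (MALDI-TOF/TOF scale; the source experiment
does not state one) and is exposed as a parameter.

Evidence from differently opened precursors of the same cyclic parent
(GluC vs. trypsin) is merged by mapping each linear position back to
cyclic coordinates and OR-ing support.

Ile/Leu resolution prices every arc of the parent bounded by candidate
chymotryptic sites (definite F/Y/W/L/M plus each ambiguous J position)
and matches arcs against observed fragment masses. A matched arc whose
boundary falls immediately after a J argues Leu; a J strictly inside a
matched arc argues Ile; Leu evidence wins over spanning evidence because
incomplete digestion can span a genuine Leu. Full-length single-cut arcs
of a cyclic parent are ignored — their mass is identical for every cut
position, so they localize nothing. Output is evidence-graded
(`chymotryptic_cleavage` / `homology` / `none`); homology-based calls are
accepted from the caller, never inferred silently.

## Inhibition analytics

Percent remaining activity is I = 100·v_i/v_o after subtracting the
substrate-only background from both velocities. Michaelis–Menten and 4PL
fits use `scipy.optimize.curve_fit` (trust-region least squares). The
4PL is fitted on replicate means by default (per-replicate fitting
optional), with starting values Top = max(Y), Bottom = min(Y), LogIC50 =
X nearest the half response, Hill = −1, and Hill bounded to [−10, 10].
Concentrations are handled as log10 of the input unit; µg/mL inputs pass
through unconverted with the unit echoed in output. Remaining-activity
curves give negative Hill slopes under this parameterization. The fit is
canonicalized to Bottom ≤ Top (the 4PL is invariant under swapping
Top/Bottom and negating the Hill slope). Velocities are rescaled to O(1)
internally so raw-signal units around 1e-4 do not trip the optimizer's
gradient tolerance.

A fit is flagged non-converged when the optimizer fails, a standard error
is non-finite, the fitted curve is flat (|Top−Bottom| negligible), or the
fitted LogIC50 lies outside the dosed range — the transition was never
bracketed, as in a design with all doses far above the IC50. No automatic
outlier rejection is performed. Normalization to the maximum response is
applied before fitting when requested; normalizing after fitting instead
only rescales Top/Bottom and leaves LogIC50 and Hill unchanged, so the
default (before) is also the order-insensitive choice for the reported
quantities.

## Sequence analytics

Loop decomposition takes the written cyclotide convention literally: the
first Cys in the string is Cys I, loop i lies strictly between Cys i and
Cys i+1, and loop 6 wraps through the ligation site. The loop *multiset*
is rotation-invariant by construction (tested over all rotations); loop
*numbering* — and therefore the Moebius/bracelet call, which looks for
Pro in loop 5 — depends on the anchoring, which cannot be recovered from
sequence alone, so classification is guaranteed invariant only under
rotations that stay within loop 6. The subtype call is a sequence-level
proxy for cis-Pro geometry and every output carries that caveat.

Identity scoring (match 1, mismatch 0, free gaps) is exactly the longest
common subsequence, computed by dynamic programming and cross-checked
against an exponential recursive oracle in tests. Whether the original
scoring was global or local is unstated; both modes are exposed, and
under this degenerate scoring they coincide, so global is the default.
Homology ranking sorts by score, ties by id, and reports score divided by
the shorter length; an optional mode scores the best cyclic rotation of
the query. Frequency matrices report per-column residue frequencies over
non-gap characters with the gap fraction separate; logo rendering is a
thin optional matplotlib layer — the tested artifact is the matrix.

## Synthetic data

The generators define the study conditions the tests run under:

* **Peptides**: cyclic 27–34-mers with exactly six cysteines, one Glu
  placed in loop 1 (so GluC opens the ring at a single site), and an
  Asn/Asp ligation residue closing loop 6. Loop-length ranges
  (1: 3–4, 2: 3–4, 3: 4–6, 4: 1, 5: 4–5, 6: 6–8) and a residue alphabet
  weighted toward Violaceae cyclotide usage put native [M+H]+ inside the
  2,900–3,550 Da screening window; draws outside it are rejected.
* **Peak lists**: mass error is modeled as per-measurement calibration
  drift relative to the previously observed derivatization state, so each
  chaining step deviates by N(0, σ_ppm) (default 10 ppm) and errors
  accumulate along the quadruple. This matches the
  `from_previous_observed` matcher and makes step containment a 3σ
  statement at 8 ppm noise / 25 ppm tolerance. Decoy peaks are uniform
  over each list's window, redrawn within 3×25 ppm of any true peak so
  false-positive tests are well-posed; dropout removes peaks from
  configurable lists (default: linearized only).
* **MS/MS**: each base ion appears with probability 0.8, each loss
  satellite with 0.2, with 0.05 Da jitter and 10 uniform noise peaks.
* **Dose-response**: responses follow the 4PL at configurable truth
  (default IC50 4.4 µM, Hill −2.8, Top 100, Bottom 0) with multiplicative
  Gaussian noise (CV 5%), 10 geometric doses 0.1–60 µM, 6 replicates.

One seeded `numpy` generator is threaded through all draws; identical
configs give identical outputs, and every generator emits ground truth.

What the generators do *not* emulate: MALDI ionization-efficiency and
intensity structure, isotope envelopes, chromatography, peak-picking
artifacts, and real biological sequence correlations. Passing recovery
tests therefore demonstrate correctness of the matching/fitting logic
under the stated error model, not robustness to raw-spectrum processing.

## Problem sizes and test design

The simulation studies run at the designs the methods are meant for:
dose-response recovery uses 500 simulated experiments (8 doses × 5
replicates; median fitted IC50 within 15% of truth) and 500 experiments
at the default sextuplicate 10-dose design for ±2 SE coverage ≥ 90%.
Screening recovery uses 500 planted peptides as 25 extracts of 20 — the
per-extract density the derivatization experiment operates at (the
source extracts carried ~18 peptides each); a single 500-peptide extract
would space peaks ~1.3 Da apart, a regime where quadruple chaining is no
longer well-posed for any tolerance near 25 ppm. The full suite runs in
well under a minute.

## Known limitations

* Observed digest tables can contain transcription-level inconsistencies;
  four published alca fragment masses (261.7, 2756.3, 1494.8, 2074.8) sit
  0.5–0.9 Da off the theory implied by their own sequences and chemistry,
  and the alca 2 GluC precursor prints 0.22 Da below theory. The tables
  are kept verbatim in `refdata` with flags; theoretical values are the
  package's output.
* Subtype classification cannot see cis/trans proline geometry.
* The screen assumes centroided peak lists; no profile-data peak picking.
* Mechanistic inhibition-mode analysis (competitive vs. allosteric) is
  out of scope; [S] = K_m assay design is documentation only.
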