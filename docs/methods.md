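# Methods

## The problem

Deep brain stimulation (DBS) delivers ~130 Hz trains of very narrow
(~140 us) biphasic current pulses. Recording MEG with the stimulator on
contaminates the data in two ways: the pulse train itself (whose square-wave
harmonics extend far beyond any practical sampling rate, so under-sampling
folds pulse energy into spurious "aliased" peaks across the whole spectrum),
and movement of the stimulator's extension wires (pulsation-like motion of
magnetised hardware producing strong low-frequency artefacts on nearby
channels). This package reproduces, on fully synthetic data, a phantom
study design for comparing four sensor-level artefact-rejection methods
against a known ground truth.

## The synthetic phantom session

`megdbs.phantom.make_condition_set` simulates four linked recordings on one
sensor array from shared seeded noise streams:

* `empty_room` - white sensor noise (default 3 fT/sqrt(Hz), a realistic
  SQUID floor) plus fixed-topography line-noise sinusoids at 50-550 Hz with
  seeded phases;
* `reference` - empty room plus a sinusoidal current dipole (default
  50 nA*m, tangential, at 60% of the 7.5 cm sphere radius) oscillating at
  12 Hz;
* `dmw` - reference plus the movement/wire artefact;
* `dsmw` - dmw plus the (movement-coupled) stimulation artefact.

Because the noise streams are shared, `dsmw` decomposes exactly into
`reference` + wire term + stimulation term, which the tests verify sample
for sample.

Key modelling choices:

* **Forward model.** A homogeneous conducting sphere (closed-form solution
  for a current dipole) is exact for a spherical phantom and is used both
  to synthesise data and to build the beamformer leadfield, so simulator
  and source analysis cannot disagree about the physics.
* **Sensors.** 128 point magnetometers on the upper 60% of a 12 cm sphere,
  nominally radial with a seeded ~8.6 degree mounting tilt. The tilt is
  essential, not cosmetic: for exactly radial sensors at a single radius
  the interior and exterior multipole fields have identical angular
  profiles, making the inner/outer separation used by signal space
  separation singular. Any real helmet breaks this degeneracy through
  orientation scatter; the tilt models that.
* **Acquisition chain.** Pulses are rendered at 192 kHz, low-pass filtered
  with a 4th-order filter at 0.4 x 19.2 kHz, decimated to 19.2 kHz and then
  polyphase-decimated to 2400 Hz. The shallow first-stage filter lets pulse
  harmonics above Nyquist fold into the acquisition band; with a 130 Hz
  train and these rates the folded lines land at non-multiples of 130 Hz
  (all at multiples of 10 Hz, never inside the 11.5-12.5 Hz dipole band).
* **Stimulation topography.** Half deep electrode (current dipole inside
  the sphere), half lead-wire contribution (magnetisation dipoles on the
  phantom surface, where the stimulation current actually flows through the
  taped wires). The surface-proximal part is what leaks into the SSS
  residual space and makes the artefact detectable by tSSS's subspace
  intersection - mirroring why tSSS works on real recordings.
* **Movement.** Raised-cosine inflation (40 ms) to 3 mm every 2.5 s with a
  uniformly jittered 0.5-1.0 s deflation; >95% of displacement power lies
  below 5 Hz. The wire amplitude is fixed so that the dipole+movement
  condition carries ~10x the reference power below 5 Hz. When stimulation
  and movement are both on, the stimulation waveform is multiplied by
  (1 + displacement / 3 mm), coupling the two artefacts.
* **Clock detuning.** The dipole generator runs ~50-100 ppm off the nominal
  12 Hz (seeded). Independent instruments are never exactly commensurate;
  with mathematically exact 12 and 130 Hz the two deterministic waveforms
  share a common 0.5 s period and carry genuinely high mutual information,
  which would make any MI-based selection reject the dipole itself. This is
  a property of deterministic signals, not an estimator artefact - the same
  reason line noise must be notched out before ICA-MI (50 Hz harmonics and
  130 Hz share a 10 Hz common period).
* **Calibration.** The stimulation gain is bisected until the channel-mean
  log10 Welch spectrum of `dsmw` puts the DBS peak 1.75 (+/-0.02) above the
  12 Hz peak, matching a patient-like DBS/alpha power ratio.

## The cleaning methods

All four map `Recording -> Recording` and preserve shape, rate and
realness.

* **Hampel filter** (`cleaning.hampel_clean`). Full-length FFT per channel;
  a 6 Hz sliding window moves bin by bin over the one-sided spectrum; a bin
  whose real (or imaginary) part deviates from the window median by more
  than C x 1.4826 x MAD is replaced by that median. In `dbs_band` mode the
  identifier runs only inside +/-3 Hz bands around every stimulation
  harmonic. Window statistics are C-independent and cached across sweeps;
  they are computed in single precision (the identifier only thresholds
  against them).
* **S3P** (`cleaning.s3p_clean`). STFT with 4 s Kaiser(beta=14) windows and
  50% overlap (0.25 Hz resolution); per frequency, the cross-spectral
  density over windows is eigen-decomposed and the leading k eigenvectors
  are projected out of every window's coefficient vector; square-window
  normalised overlap-add reconstructs the signal (the record is zero-padded
  by one hop per side so every sample is covered by two windows; k=0 is the
  identity to 1e-6).
* **ICA-MI** (`cleaning.ica_mi_clean`). PCA to 75% of the channel count,
  whitening, extended Infomax on 8x temporally decimated samples, then a
  few full-rate symmetric fixed-point iterations to polish the rotation.
  The polish matters quantitatively: subtracting an artefact component
  whose unit-variance time course carries estimation noise injects
  (1 - rho^2) x (artefact variance) of broadband noise into the sensors, and
  with a ~1e4 x noise-floor artefact the decimated estimate (rho ~ 0.994)
  injects an order of magnitude more noise than the polished one
  (rho ~ 0.9971, which equals the information-theoretic ceiling measured by
  directly regressing the true stimulation waveform on the data).
  Components are ranked by rank-transformed 64-bin histogram mutual
  information with the DBS reference channel (notched at 12 Hz), and the
  top ceil(R% x m) are removed.
* **tSSS** (`cleaning.tsss_clean`). Interior (order 8) and exterior
  (order 3) multipole field bases evaluated at the sensors (central
  differences of the scalar potentials, columns normalised); per
  non-overlapping 10 s segment a truncated-pseudoinverse least-squares fit
  splits the data into inner, outer and residual parts; canonical
  correlations between the temporal subspaces of inner and residual
  identify leaked artefacts, and directions correlating above CL are
  projected out of the inner reconstruction. Residual temporal directions
  carrying less than 0.1% of the segment's leading inner singular value are
  not intersection candidates - without this floor, the rank-1 multipole
  truncation error of a perfectly representable interior source (correlation
  exactly 1 with the source itself) would cancel the signal on noiseless
  data. Segment means (not representable by the multipole basis) are not
  restored.
* **Baseline correction** (`cleaning.baseline_correct`). tSSS reconstructs
  the interior field and therefore drops part of the sensor noise, shifting
  every channel's broadband log power; the correction subtracts the
  per-channel mean log10-power offset against the reference over 15-125 Hz
  (excluding 49-51 and 99-101 Hz) from the cleaned spectrum.

## Evaluation

Band-wise RMSE of per-channel mean log10 power (4 s Hamming Welch, 50%
overlap, density scaling) between cleaned DSMW and reference, in three
bands: dipole 11.5-12.5 Hz, movement 1-15 Hz excluding 11.5-12.5 Hz, DBS
detected peak +/-1 Hz. Line noise is notched out of all conditions before
any cleaning or evaluation. Sweeps cover C in 1-8, k in 1-9, R in 5-40%,
CL in 0.95-0.60; robustness is mean +/- sample SD of RMSE over the sweep
(DBS band only for Hampel/S3P, all bands pooled for ICA-MI/tSSS); the
optimal sensor-level parameter minimises the unweighted mean of the three
band RMSEs (ties broken toward weaker cleaning), and the source-level rule
walks the parameter sequence while the D overlap still improves by > 0.01.

Source level: 5 mm grid clipped to 95% of the sphere radius, free-
orientation leadfield, vector unit-gain LCMV after whitening with the
regularised empty-room covariance (eigenvalues below the median are raised
to the median). The per-voxel 3x3 gain matrix is rank-2 by physics (the
radial orientation is silent in a sphere), so it is inverted on its
numerically significant eigenspace; unit gain holds on that non-silent
subspace. Activation is thresholded at the 95th percentile of 1000
bootstrap resamples of the per-window power means (for non-reference maps,
voxels active in the reference are excluded from the percentile pool), and
map correspondence is the intersection-over-union measure D.

## Problem sizes

The default simulated session is 128 channels x 120 s at 2400 Hz; the
calibration check runs at that scale. The method-comparison tests run on a
60 s session (identical generator settings otherwise) and the wide-band
Hampel/S3P comparison on its first 30 s; grids use 5 mm spacing (~12k
voxels) except where unit tests use coarser lattices. These sizes are the
package's own test scale; all operations accept full-scale inputs.

## What the generator does and does not emulate

It reproduces: the linked-condition design with a known ground truth, the
aliasing mechanism of under-sampled pulse trains, movement-coupled wire
artefacts with posterior topography, line noise, patient-calibrated
artefact-to-signal ratio, and artefact leakage into the SSS residual space.
It does not emulate: vendor electronics and compensation (3rd-order
gradients, vendor SSP), SQUID jumps, gradiometer arrays, non-vertical or
irregular movement, an implanted pulse generator, or environmental noise
with realistic spatial correlation (the noise floor is white and flat).
Passing tests therefore demonstrate the methods' behaviour under this
idealised regime, not their performance on any particular real recording.

## Known limitations

* With shared noise seeds across conditions, effects far below any real
  run-to-run variability become measurable. One consequence: removing the
  DBS artefact also removes its coherent Hamming-window sidelobe leakage
  (about -64 dB) into the dipole band, so narrow-band Hampel/S3P *improve*
  the dipole-band RMSE by a few 1e-6 - a real property of the shared-seed
  design, impossible to observe with independently recorded conditions.
* In this very clean phantom regime (dipole peak ~4 orders of magnitude
  above the white noise floor), ICA time-course subtraction is limited by
  the extraction ceiling described above; the residual artefact after
  ICA-MI is accordingly larger, relative to S3P, than in noisier real
  recordings.
* The tSSS sweep is flat over CL 0.60-0.95 here: the artefact's
  inner/residual canonical correlations sit above 0.99 and everything else
  below 0.6, so every CL in the swept range removes exactly the same
  subspace.
* The mutual-information estimator is biased upward by ~0.02 bits
  (64x64 bins, ~1.4e5 samples); rankings are unaffected since the bias is
  common to all components.
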