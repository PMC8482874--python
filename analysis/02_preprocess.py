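#!/usr/bin/env python
"""Temporal preprocessing: discard 5 volumes, detrend, band-pass 0.01-0.08 Hz.

Reads scratch/cohort_raw/, applies the fixed-order temporal pipeline
(120 -> 115 timepoints, linear detrend, zero-phase 4th-order Butterworth)
and writes scratch/cohort_preprocessed/.
"""

from pathlib import Path

from dnrfc import cohort as coh
from dnrfc import preprocess as pp

SCRATCH = Path(__file__).resolve().parent.parent / "scratch"

subjects = coh.read_cohort(SCRATCH / "cohort_raw" / "manifest.csv")
config = pp.PreprocessConfig(n_discard=5, band_low_hz=0.01, band_high_hz=0.08,
                             tr_seconds=3.0)
cleaned = [
    coh.SubjectSeries(s.subject_id, s.label, pp.preprocess_subject(s.series, config))
    for s in subjects
]
manifest = coh.write_cohort(cleaned, SCRATCH / "cohort_preprocessed")
print(f"preprocessed {len(cleaned)} subjects: "
      f"{subjects[0].series.shape} -> {cleaned[0].series.shape}")
print(f"wrote {manifest.parent}")
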