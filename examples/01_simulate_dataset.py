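"""Generate a small coupled EEG-fMRI dataset and write it to disk.

The simulator plants two alpha-coupled networks (an arousal-like one in
subcortex, a visual-like one in occipital cortex) plus a systemic delta
component, drives occipital EEG band power from the same latents, and
injects motion spikes and 45 Hz EEG bursts.
"""

import numpy as np

import crossband as cb
from crossband.io import write_dataset

cfg = cb.scaled_config(n_subjects=3, run_length_tr=600, seed=0)
dataset, truth = cb.generate_dataset(cfg)
write_dataset(dataset, "example_dataset", truth)

print(f"subjects: {dataset.subjects}")
print(f"regions:  {len(dataset.atlas)} "
      f"({len(dataset.atlas.regions_of_class('cortical'))} cortical, "
      f"{len(dataset.atlas.regions_of_class('subcortical'))} subcortical, "
      f"{len(dataset.atlas.regions_of_class('nongray'))} non-gray)")
run = dataset.runs[0]
print(f"run length: {run.parcels.n_tr} TRs at {run.parcels.tr_seconds} s "
      f"({run.parcels.n_tr * run.parcels.tr_seconds / 60:.1f} min)")
key = "sub-01/run-01"
print(f"planted artifacts in {key}: {len(truth.artifact_tr_indices[key])} TRs")
mix = truth.latent_mix("sub-01", "run-01", "alpha")
print(f"alpha latent mix sd: {np.std(mix):.2f} (drives EEG alpha power)")
print("wrote example_dataset/ (parcel TSVs, motion TSVs, EEG CSVs, ground truth)")
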