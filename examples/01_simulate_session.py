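"""Generate a synthetic drug session and write it to disk.

The generator emulates one day-0 recording: baseline rest + task blocks, an
intraperitoneal injection, then three rest and two task blocks (60-s blocks
standing in for the 15-min study blocks).  Drug sessions gain a ~100 Hz
narrowband LFP oscillation peaking in infralimbic cortex, a net suppression
of unit firing, and reduced spike-train entropy.
"""

import numpy as np

from pfcdyn.synthetic_data import SimParams, make_experiment

params = SimParams(seed=42)
lfp, units, schedule = make_experiment(params, drug="psi_0.3",
                                       out_dir="scratch/example_session",
                                       seed=42)

rates = [u.n_spikes / schedule.t_end for u in units]
print(f"schedule: {len(schedule.blocks)} blocks, injection at "
      f"{schedule.injection_time:.0f} s, drug={schedule.drug}")
print(f"LFP: {lfp.data.shape[0]} samples x {lfp.data.shape[1]} channels "
      f"at {lfp.fs:.0f} Hz")
print(f"units: {len(units)} across IL/PL/CG, median rate "
      f"{np.median(rates):.2f} Hz")
# The median rate sits near the generator's log-normal baseline (2.5 Hz);
# the session directory now holds lfp.h5, spikes.csv/units.csv, schedule.yaml.
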