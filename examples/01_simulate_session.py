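"""Simulate a stimulation session and inspect its structure.

Builds a compact synthetic session (24 electrodes instead of 96, otherwise
the default task: 800 ms fixation, +/-7 deg jumps, 20-trial blocks with 50%
stimulation at 100 and 250 uA) and prints the block structure and the
electrode-grid split.  The printed counts show that stimulation and jump
directions are balanced by construction, which is what makes the
stimulated-vs-control contrasts downstream interpretable.
"""

from oculostim import SimConfig, simulate_session

cfg = SimConfig(n_electrodes=24, grid_shape=(4, 6), evoking_electrodes=())
session = simulate_session(cfg, seed=1)

trials = session.trials
print(f"trials: {len(trials)} "
      f"({cfg.n_electrodes} electrodes x {len(cfg.currents_uA)} currents "
      f"x {cfg.trials_per_block} trials)")
print(f"stimulated: {int(trials['stim'].sum())} (exactly half)")
print(trials.groupby(['current_uA', 'jump_dir']).size())
print("\nelectrode groups:")
print(session.electrode_map['group'].value_counts())
trace = session.trace(0)
print(f"\ntrace 0: {trace.n_samples} samples at {trace.sample_rate:.0f} Hz "
      f"({trace.t_ms[-1] + trace.dt_ms:.0f} ms)")
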