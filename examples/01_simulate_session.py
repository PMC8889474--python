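"""Simulate one participant's VR cue-exposure session and inspect the log.

Generates the full six-scene session (100 Hz tracker timeseries + events)
for a single synthetic participant and prints what a session looks like:
the pseudorandomized scene order, per-scene sample/event volumes, and the
post-scene craving ratings.
"""

from vreye import SimConfig, simulate_participant

config = SimConfig(seed=7)
log, truth = simulate_participant(config, participant_index=0)

print(f"participant {log.participant_id}")
print(f"scene order: {' -> '.join(log.scene_order)}")
print(f"baseline surveys: {log.baseline_surveys}")
print(f"90-day use episodes (ground truth): {truth.use_episodes:.0f}")
print()
print(f"{'scene':<12} {'type':<8} {'samples':>8} {'events':>7} {'craving':>8}")
for name in log.scene_order:
    session = log.sessions[name]
    print(f"{name:<12} {session.scene_type:<8} {len(session.samples):>8} "
          f"{len(session.events):>7} {truth.scenes[name].craving:>8}")

# The scene order alternates Active (cue-containing) and Neutral scenes;
# craving ratings are 0-100 VAS responses collected after each scene and
# should run higher after Active scenes.
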