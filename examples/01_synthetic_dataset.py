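"""Build a synthetic multi-camera phase-scripted dataset with known truth.

The factory mirrors the reference recording design — participants x
recordings x cameras — and each workflow script assigns every phase a
distinct motion direction and active region per camera.
"""

import phaseflow as pf

scripts = pf.make_dataset(participants=7, recordings_per_participant=4, cameras=3)
print(f"workflows: {len(scripts)}")
print(f"video streams: {sum(s.cameras for s in scripts)}")
print(f"phases per workflow: {scripts[0].n_phases}")

# render one workflow to actual frames
sequences, annotation = pf.generate_phase_videos(scripts[0])
print(f"\nrendered workflow {scripts[0].workflow_id}: "
      f"{len(sequences)} cameras x {sequences[0].n_frames} frames "
      f"({sequences[0].frame_shape[1]}x{sequences[0].frame_shape[0]} px, "
      f"{sequences[0].fps} fps)")
print("phase plan (index, start second, length):")
for segment in annotation.segments:
    print("  ", segment)

# Each line is one phase of the scripted workflow; the pipeline's job is to
# recover these start times and lengths from pixel motion alone.
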