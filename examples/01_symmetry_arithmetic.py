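"""Helical-parameter arithmetic: pitch/units-per-turn vs twist/rise.

A filament with a pitch of 17.26 Å and 3.56 subunits per turn is the same
helix as one with -101.124° twist and 4.848 Å rise (left-handed).  The
rational repeat tells you after how many subunits the structure repeats.
"""

from helifil import (
    SegmentationParams,
    asymmetric_units,
    pitch_units_to_symmetry,
    rational_units_per_turn,
    repeat_distance,
)

sym = pitch_units_to_symmetry(pitch_ang=17.26, units_per_turn=3.56, handedness="left")
print(f"twist = {sym.twist_deg:.3f} deg, rise = {sym.rise_ang:.3f} A")

rep = rational_units_per_turn(3.56, max_turns=10)
print(f"repeat: u = {rep.u} subunits in t = {rep.t} turns")
print(f"repeat distance c = {repeat_distance(rep.u, 4.87):.1f} A")

seg = SegmentationParams(segment_length_ang=400.0, step_ang=70.0, n_segments=9661)
print(f"asymmetric units contributed by 9661 segments: {asymmetric_units(seg, 4.848)}")
# Each segment contributes floor(step / rise) unique subunits; the printed
# total is what enters the reconstruction statistics.
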