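"""Compute the PCECV and ICPCV feature vectors for one observation.

PCECV normalizes corner-to-pupil vectors by the eye's corner distance
and averages them (similarity invariant); ICPCV keeps the raw inner
corner -> pupil vector per eye, plus three head-pose proxies: CES
(inner-corner midpoint), DES (inner-corner distance) and TA (tilt of
the inter-corner line).
"""

import icpcv

params = icpcv.GazeModelParams(head_translation=(12.0, -5.0), head_yaw=2.0)
obs = icpcv.simulate_observation((1400.0, 300.0), params, seed=3)

ic = icpcv.assemble_icpcv(obs)
print(f"CES  (head position proxy) : {ic.ces.round(2)} px")
print(f"DES  (head distance proxy) : {ic.des:.2f} px")
print(f"TA   (head roll proxy)     : {ic.ta:.2f} deg")
print(f"ICPCV left / right         : {ic.icpcv_left.round(2)} / {ic.icpcv_right.round(2)}")
print(f"full 8-vector              : {ic.full8.round(2)}")

pc = icpcv.features.pcecv_feature(obs)
print(f"PCECV theta                : {pc.theta.round(4)}")
print(f"expanded quadratic vector  : {pc.expanded.round(4)}")
# TA reflects the 2 deg head roll; the ICPCV components move with gaze
# while CES/DES/TA track only the head pose.
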