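"""Estimate the posture of one synthetic occluded cabbage.

Generates a scene whose true axis tilt is 25 degrees with 30% of the root
hidden by the outer-leaf line, runs the Bezier growth-curve pipeline and
prints the recovered keypoints and angle.  The predicted theta should land
within a couple of degrees of the true 25; the label compares theta with the
cutting threshold beta.
"""

from cabbagepose import SceneParams, generate_scene, predict_posture

scene, truth = generate_scene(
    SceneParams(true_angle_deg=25.0, root_curvature=0.4,
                occlusion_frac=0.3, noise_frac=0.02, seed=42)
)
result = predict_posture(scene, beta_deg=10.0)

print(f"true axis angle : {truth.true_angle_deg:.2f} deg")
print(f"true junction   : ({truth.true_junction[0]:.1f}, {truth.true_junction[1]:.1f})")
print(f"P0 root centroid: ({result.p0[0]:.1f}, {result.p0[1]:.1f})")
print(f"P1 breakpoint   : ({result.p1[0]:.1f}, {result.p1[1]:.1f})")
print(f"P2 head centroid: ({result.p2[0]:.1f}, {result.p2[1]:.1f})")
print(f"P3 predicted junction: ({result.p3[0]:.1f}, {result.p3[1]:.1f})")
print(f"theta           : {result.theta_deg:.2f} deg (beta = {result.beta_deg})")
print(f"posture label   : {result.label.value}")
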