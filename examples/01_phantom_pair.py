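"""Generate a matched normal/effusion phantom pair and inspect the recess.

The two phantoms share seed and anatomy; only the pleural fluid differs.
The mean intensity inside the recorded costophrenic recess is the
simplest class signal: fluid is bright, aerated lung is dark.
"""

from pleurakit import PhantomConfig, generate_phantom, recess_mean, save_image

normal = generate_phantom(PhantomConfig(seed=3))
effusion = generate_phantom(PhantomConfig(seed=3, effusion=True,
                                          fill_level=0.4, side="right"))

save_image("phantom_normal.png", normal.image)
save_image("phantom_effusion.png", effusion.image)

print(f"truth lung box: {normal.truth.lung_box}")
print(f"right costophrenic recess mean, normal:   {recess_mean(normal, 'right'):.3f}")
print(f"right costophrenic recess mean, effusion: {recess_mean(effusion, 'right'):.3f}")
print("(higher mean = bright fluid filling the recess; images written "
      "to phantom_normal.png / phantom_effusion.png)")
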