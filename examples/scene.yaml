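# One synthetic dual-channel cell scene.
cell_area: 600.0        # µm²
n_mitochondria: 30
length_mean: 2.4        # µm
length_sd: 0.7
ratio_mean: 200.0       # scaled-ratio units
ratio_sd: 40.0
pixel_size_xy: 0.08     # µm/pixel
z_step: 0.25            # µm
n_planes: 9
psf_fwhm_xy: 0.4        # µm
psf_fwhm_z: 1.4         # µm
noise_level: 200.0      # photons per unit intensity (0 = noise-free)
decoys: false           # inject border/fused/pixel/oversized filter probes
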