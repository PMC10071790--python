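# Synthetic S-value matrix (mGy per MBq*h), adult-male-style magnitudes.
# Placeholder stand-in for a phantom Monte-Carlo library; exercises the
# dose formalism only and carries no dosimetric authority.
source,target,mGy_per_MBq_h
liver,liver,0.08
liver,spleen,0.004
liver,kidneys,0.004
liver,lung,0.004
liver,heart,0.004
liver,red_marrow,0.004
liver,colon,0.004
liver,stomach,0.004
liver,breast,0.004
liver,gonads,0.004
liver,bladder,0.004
liver,oesophagus,0.004
liver,thyroid,0.0008
liver,bone_surface,0.0008
liver,brain,0.0008
liver,salivary_glands,0.0008
liver,skin,0.0008
spleen,liver,0.004
spleen,spleen,0.35
spleen,kidneys,0.004
spleen,lung,0.004
spleen,heart,0.004
spleen,red_marrow,0.004
spleen,colon,0.004
spleen,stomach,0.004
spleen,breast,0.004
spleen,gonads,0.004
spleen,bladder,0.004
spleen,oesophagus,0.004
spleen,thyroid,0.0008
spleen,bone_surface,0.0008
spleen,brain,0.0008
spleen,salivary_glands,0.0008
spleen,skin,0.0008
kidneys,liver,0.004
kidneys,spleen,0.004
kidneys,kidneys,0.2
kidneys,lung,0.004
kidneys,heart,0.004
kidneys,red_marrow,0.004
kidneys,colon,0.004
kidneys,stomach,0.004
kidneys,breast,0.004
kidneys,gonads,0.004
kidneys,bladder,0.004
kidneys,oesophagus,0.004
kidneys,thyroid,0.0008
kidneys,bone_surface,0.0008
kidneys,brain,0.0008
kidneys,salivary_glands,0.0008
kidneys,skin,0.0008
lung,liver,0.004
lung,spleen,0.004
lung,kidneys,0.004
lung,lung,0.06
lung,heart,0.004
lung,red_marrow,0.004
lung,colon,0.004
lung,stomach,0.004
lung,breast,0.004
lung,gonads,0.004
lung,bladder,0.004
lung,oesophagus,0.004
lung,thyroid,0.0008
lung,bone_surface,0.0008
lung,brain,0.0008
lung,salivary_glands,0.0008
lung,skin,0.0008
heart,liver,0.004
heart,spleen,0.004
heart,kidneys,0.004
heart,lung,0.004
heart,heart,0.15
heart,red_marrow,0.004
heart,colon,0.004
heart,stomach,0.004
heart,breast,0.004
heart,gonads,0.004
heart,bladder,0.004
heart,oesophagus,0.004
heart,thyroid,0.0008
heart,bone_surface,0.0008
heart,brain,0.0008
heart,salivary_glands,0.0008
heart,skin,0.0008
red_marrow,liver,0.004
red_marrow,spleen,0.004
red_marrow,kidneys,0.004
red_marrow,lung,0.004
red_marrow,heart,0.004
red_marrow,red_marrow,0.04
red_marrow,colon,0.004
red_marrow,stomach,0.004
red_marrow,breast,0.004
red_marrow,gonads,0.004
red_marrow,bladder,0.004
red_marrow,oesophagus,0.004
red_marrow,thyroid,0.0008
red_marrow,bone_surface,0.0008
red_marrow,brain,0.0008
red_marrow,salivary_glands,0.0008
red_marrow,skin,0.0008
remainder,liver,0.003
remainder,spleen,0.003
remainder,kidneys,0.003
remainder,lung,0.003
remainder,heart,0.003
remainder,red_marrow,0.003
remainder,colon,0.003
remainder,stomach,0.003
remainder,breast,0.003
remainder,gonads,0.003
remainder,bladder,0.003
remainder,oesophagus,0.003
remainder,thyroid,0.003
remainder,bone_surface,0.003
remainder,brain,0.003
remainder,salivary_glands,0.003
remainder,skin,0.003
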