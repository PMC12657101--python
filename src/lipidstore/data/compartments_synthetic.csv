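compartment,mass_frac_mean,mass_frac_sd,p_water_mean,p_water_sd,p_lipid_mean,p_lipid_sd,p_protein_mean,p_protein_sd,p_ash_mean,p_ash_sd
Skeleton,0.105,0.01,0.312899,0.035,0.2744,0.04,0.228558,0.025,0.184143,0.025
Muscle,0.335,0.025,0.658191,0.03,0.05831,0.02,0.274369,0.025,0.00913,0.002
Organs,0.045,0.006,0.717439,0.03,0.079095,0.025,0.194177,0.02,0.009289,0.002
Viscera,0.065,0.008,0.671553,0.035,0.148734,0.035,0.170398,0.02,0.009316,0.002
Blubber,0.245,0.028,0.381238,0.045,0.462988,0.07,0.151147,0.02,0.004627,0.001
Sound production apparatus,0.085,0.01,0.335301,0.045,0.544585,0.07,0.115463,0.02,0.004651,0.001
Other,0.07,0.008,0.567391,0.04,0.195478,0.04,0.227949,0.025,0.009183,0.002
Blood,0.05,0.006,0.763061,0.02,0.009858,0.005,0.217819,0.02,0.009262,0.002
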