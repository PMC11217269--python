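date,week,site,snow_depth_cm,snow_depth_sd,albedo_pct,ice_thickness_cm,ice_thickness_sd,ice_temperature_c,bulk_salinity_ppt,brine_salinity_ppt,brine_volume_pct,chl_a_ice,chl_a_ice_sd,cn_ratio,d13c,d15n,si_um,nox_um,po4_um,chl_a_water,cn_ratio_water,d13c_water,d15n_water,si_water_um,nox_water_um,po4_water_um,water_temperature_c
2022-04-06,1,outer,15,0.7,76,64,1,-2.3,10.80,40.78,24,0.52,1,6.14,-25.01,3.81,,0.98,0.24,0.29,4.95,-31.31,2.04,15.61,7.46,0.51,-1.79
2022-04-07,1,inner,22,2,95,83,2,-2.1,9.74,37.36,23,0.31,1.9,2.75,-26.81,3.26,2.51,2.46,0.34,0.02,3.99,-28.91,2.56,15.37,7.62,0.51,-1.79
2022-04-20,3,inner,27,4,77,85,0.5,-2.6,13.14,45.85,26,2.00,0.1,5.40,-21.95,2.49,3.93,5.65,0.47,0.04,3.16,-26.5,2.18,9.62,5.52,0.40,-1.87
2022-04-21,3,outer,27,2,94,70,1,-2.7,12.33,47.53,23,0.49,0.3,2.62,-27.14,1.48,,3.19,0.30,0.31,2.57,-26.86,4.69,14.48,7.22,0.53,-1.85
2022-04-29,4,outer,19,5,90,73,3,-2.5,9.78,44.15,19,1.32,0.2,4.79,-22.65,2.88,0.38,2.01,0.40,0.25,5.67,-24.83,4.03,11.33,5.70,0.45,-1.65
2022-04-30,4,inner,28,0.5,93,90,1,-2.3,13.00,40.78,28,2.91,0.8,3.24,-22.92,0.96,1.38,9.90,0.60,0.28,4.85,-26.08,3.49,12.84,7.17,0.41,-1.87
2022-05-12,6,inner,32,1.5,78,85,3,-2.3,8.90,40.78,19,2.03,0.5,4.04,-23.41,3.05,0.45,1.79,0.65,0.27,7.15,-24.73,4.25,12.13,6.44,0.47,-1.50
2022-05-13,6,outer,9,1,88,74,1,-2.6,7.34,45.85,14,4.33,1.6,11.51,-16.29,4.24,1.37,0.60,1.62,0.88,6.33,-25.17,4.6,3.86,2.52,0.31,-1.67
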