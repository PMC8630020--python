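# Properties of the eight open-ocean sediment cores the presets emulate.
region,core_id,coring_method,latitude,longitude,water_depth_m,organic_matter_content_pct,sedimentation_rate_m_yr
Arabian Sea,SAST,multiple-coring,10 02 N,65 00 E,4424,0.05-0.4,1.2e-5
Arctic Mid-Ocean Ridge,GC04,gravity coring,72 16 N,1 42 E,2668,0.3-1.0,2.0e-5
Arctic Mid-Ocean Ridge,GC05,gravity coring,76 55 N,7 07 E,3007,0.3-1.8,2.5e-5
Arctic Mid-Ocean Ridge,GC08,gravity coring,71 97 N,0 10 E,2476,0.3-0.6,2.0e-5
Arctic Mid-Ocean Ridge,GC09,gravity coring,73 70 N,7 34 E,1653,0.2-0.5,5.0e-5
North Pond,NP_U1383E,piston coring,22 48 N,46 03 W,4476,<0.3,9.4e-6
North Pacific Gyre,NPG_11,multiple/gravity/piston coring,30 21 N,15 75 W,6000,,1.0e-6
South Pacific Gyre,SPG_U1370,piston coring,41 51 S,153 06 W,5075,0-0.25,1.5e-6
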