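id,fish_copy_number,fish_ratio,density_per_um2,density_sem,per_cluster,per_cluster_sem,cluster_radius_nm,cluster_radius_sem,clustered_pct,clustered_sem,sigma_nm,sigma_sem,coverslips,n_rois,p_split
P1,6.3,2.4,24,3,3.3,0.4,25.0,1.0,34,5.0,21.1,0.5,2,30,0.3
P2,,4.4,30,3,2.9,0.7,17.0,1.0,20,4.0,14.4,0.2,3,85,0.2
P3,32.2,4.4,57,3,4.7,0.4,40.0,2.0,67,3.0,16.7,0.3,3,92,0.3
P4,4.3,2.5,15,1,2.4,0.1,18.0,1.0,21,2.0,14.8,0.2,4,88,0.3
P5,13.6,11.3,37,2,3.6,0.4,29.0,2.0,62,5.0,13.4,0.1,2,131,0.5
P6,6.3,1.6,26,1,3.0,0.4,33.0,4.0,59,5.0,14.4,0.1,4,164,0.4
P7,1.2,0.7,15,1,,,,,0,,13.3,0.2,3,46,0.5
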