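map,zone,map_class,ref_noncrop_pct,ref_crop_pct,n,area_total_km2
pixel,zone1,noncrop,64.2,9.0,138,
pixel,zone1,crop,7.7,19.1,226,
pixel,zone2,noncrop,73.9,6.7,169,
pixel,zone2,crop,6.8,12.6,247,
pixel,zone3,noncrop,89.6,4.8,177,
pixel,zone3,crop,1.6,4.0,98,
pixel,zone4,noncrop,80.7,5.3,65,
pixel,zone4,crop,5.7,8.4,87,
pixel,ghana,noncrop,77.2,6.7,549,248343
pixel,ghana,crop,5.3,10.8,658,248343
segmentation,zone1,noncrop,57.6,4.2,88,
segmentation,zone1,crop,14.4,23.8,276,
segmentation,zone2,noncrop,70.4,3.7,121,
segmentation,zone2,crop,11.2,14.8,295,
segmentation,zone3,noncrop,86.6,3.0,148,
segmentation,zone3,crop,4.3,6.1,127,
segmentation,zone4,noncrop,75.3,3.4,46,
segmentation,zone4,crop,10.4,10.8,106,
segmentation,ghana,noncrop,73.2,3.6,403,248343
segmentation,ghana,crop,9.7,13.5,804,248343
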