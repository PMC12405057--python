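profile_id,gaussian_sigma,gaussian_kernel,nlm_h,nlm_search,nlm_patch,clahe_clip,clahe_grid,thresh_block,thresh_c,close_kernel,open_kernel,min_component_px,histogram_path
default,1.5,5x5,7.0,42,29,2.2,20x20,33,9.1,5x5,2x2,10,default_hist.csv
synthetic_desk,0.6,5x5,7.0,15,7,2.2,20x20,33,26.0,5x5,2x2,60,synthetic_desk_hist.csv
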